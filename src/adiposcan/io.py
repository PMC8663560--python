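"""Volume and table I/O: NIfTI round-trips, masks as companion files.

Volumes are written as ``.nii.gz`` with an identity affine; the body mask
and the (disjoint) region masks travel as companion files next to the main
image (``<stem>_mask.nii.gz`` and a label-encoded ``<stem>_regions.nii.gz``
plus a JSON sidecar naming the labels and the axis order).  Round trips are
voxel-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import NormalizedVolume
from .synthgen import BodyVolume


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be parsed."""


def _nifti(path: Path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.eye(4)), str(path))


def _read_nifti(path: Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:
        raise VolumeFormatError(f"cannot parse {path}: {exc}") from exc


def save_volume(volume: BodyVolume | NormalizedVolume, path: str | Path) -> Path:
    """Write voxels + masks + sidecar. ``path`` names the main image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    _nifti(path, volume.voxels.astype(np.float32))
    _nifti(path.parent / f"{stem}_mask.nii.gz", volume.body_mask.astype(np.uint8))
    names = sorted(volume.region_masks)
    if names:
        enc = np.zeros(volume.voxels.shape, dtype=np.uint8)
        for i, r in enumerate(names, start=1):
            enc[volume.region_masks[r]] = i
        _nifti(path.parent / f"{stem}_regions.nii.gz", enc)
    axis_order = getattr(volume, "axis_order", ("vertical", "sagittal", "coronal"))
    sidecar = {
        "axis_order": list(axis_order),
        "region_labels": {str(i): r for i, r in enumerate(names, start=1)},
        "voxel_volume_ml": getattr(volume, "voxel_volume_ml", None),
        "subject_id": getattr(volume, "subject_id", None) or getattr(volume, "provenance", None),
    }
    (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> BodyVolume:
    """Lossless inverse of :func:`save_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    vox = _read_nifti(path).astype(np.float32)
    mask_path = path.parent / f"{stem}_mask.nii.gz"
    body = _read_nifti(mask_path).astype(bool) if mask_path.exists() else vox > 0
    sidecar_path = path.parent / f"{stem}.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    regions: dict[str, np.ndarray] = {}
    regions_path = path.parent / f"{stem}_regions.nii.gz"
    if regions_path.exists():
        enc = _read_nifti(regions_path).astype(np.uint8)
        for code, name in sidecar.get("region_labels", {}).items():
            regions[name] = enc == int(code)
    return BodyVolume(
        voxels=vox,
        body_mask=body,
        region_masks=regions,
        axis_order=tuple(sidecar.get("axis_order", ("vertical", "sagittal", "coronal"))),
        voxel_volume_ml=sidecar.get("voxel_volume_ml") or 80.0,
        subject_id=sidecar.get("subject_id"),
    )
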