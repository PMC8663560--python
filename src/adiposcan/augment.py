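"""Training-time augmentation, test-time centering, and region crops.

All transforms preserve the two intensity invariants of normalized scans:
body voxels stay strictly positive and background stays exactly 0.  Random
zero-padding translates the body inside the grid, small-angle rotations are
applied about each axis, Gaussian noise is added to body voxels only, and
an optional zoom rescales the body; the volume is then resized/cropped back
to the network input dimensions.  Validation and test volumes are centered
only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import AugmentConfig
from .preprocess import NormalizedVolume

_POSITIVE_FLOOR = 1e-4


def _recrop(vox: np.ndarray, mask: np.ndarray, dims: tuple[int, ...]):
    """Center-crop or zero-pad back to ``dims``."""
    out_v = np.zeros(dims, dtype=vox.dtype)
    out_m = np.zeros(dims, dtype=bool)
    src, dst = [], []
    for s, d in zip(vox.shape, dims):
        if s >= d:
            a = (s - d) // 2
            src.append(slice(a, a + d))
            dst.append(slice(0, d))
        else:
            a = (d - s) // 2
            src.append(slice(0, s))
            dst.append(slice(a, a + s))
    out_v[tuple(dst)] = vox[tuple(src)]
    out_m[tuple(dst)] = mask[tuple(src)]
    return out_v, out_m


def _rotate(vox: np.ndarray, mask: np.ndarray, angles: tuple[float, float, float]):
    axes_pairs = [((1, 2), angles[0]), ((0, 2), angles[1]), ((0, 1), angles[2])]
    for axes, ang in axes_pairs:
        if abs(ang) < 1e-9:
            continue
        vox = ndimage.rotate(vox, ang, axes=axes, reshape=False, order=1, mode="constant", cval=0.0)
        mask = ndimage.rotate(mask.astype(np.float32), ang, axes=axes, reshape=False, order=0, cval=0.0) > 0.5
    return vox, mask


def augment_volume(
    volume: NormalizedVolume, cfg: AugmentConfig, rng: np.random.Generator
) -> NormalizedVolume:
    """Random pad -> rotations -> body-only Gaussian noise -> optional zoom."""
    vox = volume.voxels.astype(np.float32)
    mask = volume.body_mask
    dims = vox.shape

    if cfg.pad_enabled and cfg.max_pad > 0:
        pads = [(int(rng.integers(0, cfg.max_pad + 1)), int(rng.integers(0, cfg.max_pad + 1))) for _ in range(3)]
        vox = np.pad(vox, pads)
        mask = np.pad(mask, pads)

    if cfg.rotation_enabled and (cfg.rot_vertical_deg > 0 or cfg.rot_other_deg > 0):
        angles = (
            float(rng.uniform(-cfg.rot_vertical_deg, cfg.rot_vertical_deg)),
            float(rng.uniform(-cfg.rot_other_deg, cfg.rot_other_deg)),
            float(rng.uniform(-cfg.rot_other_deg, cfg.rot_other_deg)),
        )
        vox, mask = _rotate(vox, mask, angles)

    if cfg.zoom_enabled and cfg.zoom_range > 0:
        z = float(rng.uniform(1 - cfg.zoom_range, 1 + cfg.zoom_range))
        vox = ndimage.zoom(vox, z, order=1)
        mask = ndimage.zoom(mask.astype(np.float32), z, order=0) > 0.5

    vox, mask = _recrop(vox, mask, dims)

    if cfg.noise_enabled and cfg.noise_sd > 0:
        body_sd = float(vox[mask].std()) if mask.any() else 1.0
        noise = rng.normal(0.0, cfg.noise_sd * body_sd, size=vox.shape).astype(np.float32)
        vox[mask] += noise[mask]

    vox[~mask] = 0.0
    if mask.any():
        vox[mask] = np.maximum(vox[mask], _POSITIVE_FLOOR)
    return NormalizedVolume(vox, mask, volume.region_masks, volume.provenance, volume.params)


def center_volume(volume: NormalizedVolume, cfg: AugmentConfig | None = None) -> NormalizedVolume:
    """Integer-shift the body-mask centroid to the grid center (idempotent).

    Integer shifts keep the body voxel multiset intact; vacated space is
    zero-filled.
    """
    mask = volume.body_mask
    if not mask.any():
        return volume
    centroid = np.array(ndimage.center_of_mass(mask))
    center = (np.array(mask.shape) - 1) / 2.0
    shift = np.round(center - centroid).astype(int)
    if np.all(shift == 0):
        return volume
    vox = np.zeros_like(volume.voxels)
    new_mask = np.zeros_like(mask)
    src, dst = [], []
    for s, size in zip(shift, mask.shape):
        if s >= 0:
            src.append(slice(0, size - s))
            dst.append(slice(s, size))
        else:
            src.append(slice(-s, size))
            dst.append(slice(0, size + s))
    vox[tuple(dst)] = volume.voxels[tuple(src)]
    new_mask[tuple(dst)] = mask[tuple(src)]
    regions = {}
    for r, m in volume.region_masks.items():
        rm = np.zeros_like(m)
        rm[tuple(dst)] = m[tuple(src)]
        regions[r] = rm
    return NormalizedVolume(vox, new_mask, regions, volume.provenance, volume.params)


CROP_REGIONS = ("torso", "abdomen")


def crop_region(volume: NormalizedVolume, region: str, cfg: AugmentConfig | None = None) -> NormalizedVolume:
    """Restrict to a vertical window of the body extent (torso or abdomen).

    The window is a configured fractional band of the body's vertical
    extent; everything outside is zeroed (volume dims are unchanged), so
    cropping the same region twice is a no-op.
    """
    cfg = cfg or AugmentConfig()
    if region not in CROP_REGIONS:
        raise ValueError(f"unknown crop region {region!r}; supported: {CROP_REGIONS}")
    if volume.params.get("crop_region") == region:
        return volume
    lo_f, hi_f = cfg.crop_torso if region == "torso" else cfg.crop_abdomen
    mask = volume.body_mask
    occupied = np.flatnonzero(mask.any(axis=(1, 2)))
    if occupied.size == 0:
        return volume
    top, bottom = occupied[0], occupied[-1] + 1
    extent = bottom - top
    lo = top + int(np.floor(lo_f * extent))
    hi = top + int(np.ceil(hi_f * extent))
    keep = np.zeros(mask.shape[0], dtype=bool)
    keep[lo:hi] = True
    vox = volume.voxels.copy()
    vox[~keep] = 0.0
    new_mask = mask & keep[:, None, None]
    regions = {r: m & keep[:, None, None] for r, m in volume.region_masks.items()}
    return NormalizedVolume(
        vox, new_mask, regions, volume.provenance, {**volume.params, "crop_region": region}
    )


def make_augment_fn(template_mask: np.ndarray, cfg: AugmentConfig):
    """Batch augmentation closure for the training loop.

    Operates on raw arrays ``(N, D, H, W)``; each sample's body mask is its
    own nonzero support (exact under the strictly-positive-body invariant).
    """

    def fn(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(batch)
        for i in range(batch.shape[0]):
            nv = NormalizedVolume(batch[i], batch[i] > 0)
            out[i] = augment_volume(nv, cfg, rng).voxels
        return out

    return fn
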