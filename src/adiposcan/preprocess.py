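"""Volume and label preprocessing: shape/intensity normalization, outlier
removal, label scaling, stratified partitioning.

Shape normalization is a two-stage scheme for variable-height whole-body
scans: the vertical axis (slice count 90-120) is linearly interpolated to
a fixed slice count (95 in the full-scale profile), in-plane dimensions
are already standard, and the whole grid is then downsampled (linear,
anti-aliased) to the final network input dimensions (85x110x135 in the
full-scale profile).  The coarser vertical resolution receives no further
interpolation correction.

Voxel normalization zeroes non-body voxels, standardizes body voxels to
mean 0 / SD 1 with statistics from a configurable source (shared across
scans by default, so all samples are transformed equally), truncates to a
symmetric band and shifts the distribution to strictly positive values so
body tissue stays distinct from air at exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .synthgen import BodyVolume

FOLDS = ("train", "validation", "test")


class DegenerateVolumeError(ValueError):
    """Raised when a volume has no usable body-intensity variance."""


@dataclass
class NormalizedVolume:
    """Fixed-dimension volume with provenance and the transform parameters."""

    voxels: np.ndarray
    body_mask: np.ndarray
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str | None = None
    params: dict = field(default_factory=dict)


def _resize_linear(vol: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    if tuple(vol.shape) == tuple(dims):
        return vol.astype(np.float32)
    shrinking = any(d < s for d, s in zip(dims, vol.shape))
    return resize(
        vol.astype(np.float64), dims, order=1, mode="edge",
        anti_aliasing=shrinking, preserve_range=True,
    ).astype(np.float32)


def _resize_masks(
    body: np.ndarray, regions: dict[str, np.ndarray], dims: tuple[int, int, int]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    body_f = _resize_linear(body.astype(np.float32), dims)
    new_body = body_f > 0.5
    if not regions:
        return new_body, {}
    names = list(regions)
    stack = np.stack([_resize_linear(regions[r].astype(np.float32), dims) for r in names])
    winner = np.argmax(stack, axis=0)
    support = np.max(stack, axis=0) > 0.5
    new_regions = {}
    for i, r in enumerate(names):
        new_regions[r] = (winner == i) & support & new_body
    return new_body, new_regions


def normalize_shape(
    volume: BodyVolume,
    target_dims: tuple[int, int, int] = (95, 150, 250),
    final_dims: tuple[int, int, int] | None = (85, 110, 135),
) -> NormalizedVolume:
    """Vertical interpolation to the target slice count, then grid downsampling.

    Body and region masks are carried through the same geometric transforms
    (majority/argmax assignment keeps them disjoint).
    """
    if any(d <= 0 for d in target_dims) or (final_dims and any(d <= 0 for d in final_dims)):
        raise ValueError("target and final dims must be positive")
    vox = volume.voxels
    if vox.shape[0] < 2:
        raise ValueError("need at least 2 slices along the vertical axis")

    # stage 1: vertical-only linear interpolation; in-plane dims are standard
    stage1_dims = (target_dims[0], vox.shape[1], vox.shape[2])
    vox1 = _resize_linear(vox, stage1_dims)
    if (vox.shape[1], vox.shape[2]) != tuple(target_dims[1:]):
        vox1 = _resize_linear(vox1, target_dims)
    body1, regions1 = _resize_masks(volume.body_mask, volume.region_masks, tuple(target_dims))

    # stage 2: whole-grid downsampling to the final network input dims
    out_dims = tuple(final_dims) if final_dims else tuple(target_dims)
    vox2 = _resize_linear(vox1, out_dims)
    body2, regions2 = _resize_masks(body1, regions1, out_dims)
    vox2[~body2] = 0.0

    return NormalizedVolume(
        voxels=vox2,
        body_mask=body2,
        region_masks=regions2,
        provenance=volume.subject_id,
        params={"target_dims": tuple(target_dims), "final_dims": out_dims},
    )


def identify_body(vox: np.ndarray) -> np.ndarray:
    """Background identification from the intensity histogram.

    Two-class Otsu threshold, keeping the largest connected foreground
    component as the body.
    """
    if not np.any(vox > 0):
        raise DegenerateVolumeError("no foreground voxels found")
    thr = threshold_otsu(vox)
    fg = vox > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise DegenerateVolumeError("no foreground voxels found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def body_voxel_stats(volumes: list[NormalizedVolume]) -> tuple[float, float]:
    """Pooled mean/SD over body voxels of a set of scans (e.g. the training fold)."""
    vals = np.concatenate([v.voxels[v.body_mask].ravel() for v in volumes])
    return float(vals.mean()), float(vals.std())


def normalize_voxels(
    volume: NormalizedVolume,
    stats_source: tuple[float, float] | None = None,
    truncate: float = 3.0,
    shift_eps: float = 0.01,
    use_provided_mask: bool = True,
) -> NormalizedVolume:
    """Zero background, standardize body voxels, truncate, shift positive.

    ``stats_source``: (mean, SD) shared across scans (one transform for all
    samples); ``None`` falls back to this scan's own body statistics.
    Returns a new volume whose ``params`` record the applied transform.
    """
    vox = volume.voxels.astype(np.float32).copy()
    if use_provided_mask and volume.body_mask is not None:
        body = volume.body_mask
    else:
        body = identify_body(vox)
    vox[~body] = 0.0  # background zero BEFORE any statistics

    vals = vox[body]
    if vals.size == 0 or float(vals.std()) == 0.0:
        raise DegenerateVolumeError("body voxels have zero intensity variance")
    mean, sd = stats_source if stats_source is not None else (float(vals.mean()), float(vals.std()))
    if sd <= 0:
        raise DegenerateVolumeError("nonpositive SD in stats_source")

    std = (vox[body] - mean) / sd
    std = np.clip(std, -truncate, truncate)
    shift = truncate + shift_eps
    out = np.zeros_like(vox)
    out[body] = std + shift  # minimum body value >= shift_eps > 0

    return NormalizedVolume(
        voxels=out,
        body_mask=body,
        region_masks=volume.region_masks,
        provenance=volume.provenance,
        params={
            **volume.params,
            "mean": mean, "sd": sd, "truncate": truncate, "shift": shift,
        },
    )


OUTLIER_FEATURES = ("insulin_sensitivity", "bmi", "hba1c", "total_adipose_volume")


def remove_outliers(
    feature_table: pd.DataFrame,
    contamination: float = 0.02,
    features: tuple[str, ...] = OUTLIER_FEATURES,
    seed: int = 0,
) -> np.ndarray:
    """Isolation-forest keep-mask over the four medical features.

    Returns a boolean array, True for rows to keep.  ``contamination`` is
    the expected anomaly fraction; 0 keeps every row.
    """
    missing = [f for f in features if f not in feature_table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if contamination <= 0:
        return np.ones(len(feature_table), dtype=bool)
    from sklearn.ensemble import IsolationForest

    X = feature_table.loc[:, list(features)].to_numpy(dtype=float)
    forest = IsolationForest(contamination=contamination, random_state=seed)
    return forest.fit_predict(X) == 1


CONTINUOUS_LABELS = ("age", "bmi", "insulin_sensitivity", "hba1c_pct")


def normalize_labels(
    label_table: pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_LABELS,
    train_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]], pd.DataFrame]:
    """Min-max scale continuous labels to [0, 1] using training-fold extrema.

    Returns (scaled table, per-label (min, max) inverse transforms, observed
    mask).  Missing values stay NaN and are flagged False in the mask so
    downstream losses can exclude them per head rather than dropping the
    whole subject.
    """
    out = label_table.copy()
    transforms: dict[str, tuple[float, float]] = {}
    tm = train_mask if train_mask is not None else np.ones(len(label_table), dtype=bool)
    for col in continuous:
        ref = label_table.loc[tm, col].dropna()
        lo, hi = float(ref.min()), float(ref.max())
        if hi <= lo:
            raise ValueError(f"label column {col!r} is constant on the training fold")
        out[col] = (label_table[col] - lo) / (hi - lo)
        transforms[col] = (lo, hi)
    observed = label_table.loc[:, list(continuous)].notna()
    return out, transforms, observed


def denormalize_mae(normalized_mae: float, transform: tuple[float, float]) -> float:
    """Absolute-unit MAE = normalized MAE x training range."""
    lo, hi = transform
    return normalized_mae * (hi - lo)


def _allocate(counts: np.ndarray, fractions: tuple[float, ...]) -> np.ndarray:
    """Controlled rounding: per-stratum fold counts hitting exact global totals.

    Every entry is floor(quota) or ceil(quota), so per-stratum proportions
    stay within one sample of the target fractions.
    """
    n = int(counts.sum())
    target = np.floor(n * np.asarray(fractions)).astype(int)
    for i in np.argsort(-(n * np.asarray(fractions) - target))[: n - target.sum()]:
        target[i] += 1
    quotas = counts[:, None] * np.asarray(fractions)[None, :]
    base = np.floor(quotas).astype(int)
    frac = quotas - base
    rem_global = target - base.sum(axis=0)
    need = counts - base.sum(axis=1)
    order = np.dstack(np.unravel_index(np.argsort(-frac, axis=None), frac.shape))[0]
    alloc = base.copy()
    for s, f in order:
        if need[s] > 0 and rem_global[f] > 0 and alloc[s, f] < np.ceil(quotas[s, f] + 1e-9):
            alloc[s, f] += 1
            need[s] -= 1
            rem_global[f] -= 1
    # last-resort repair (unreachable in ordinary configurations)
    for s in np.flatnonzero(need > 0):
        for f in np.argsort(-rem_global):
            take = min(need[s], rem_global[f])
            alloc[s, f] += take
            need[s] -= take
            rem_global[f] -= take
    return alloc


def stratified_split(
    label_table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    strata_vars: tuple[str, str] = ("bmi", "insulin_sensitivity"),
    binary_var: str = "diabetes",
    n_bins: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified random split into train/validation/test folds.

    Strata are tertile bins of the continuous stratification variables
    crossed with diabetes status; singleton strata are merged with the
    nearest stratum so each multivariate stratum contains more than one
    sample.  Within each stratum samples are randomly assigned at the
    target fractions.  Returns a DataFrame with ``fold`` and ``stratum``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fold fractions must sum to 1")
    n = len(label_table)
    rng = np.random.default_rng(seed)

    bin_idx = []
    for var in strata_vars:
        col = label_table[var].fillna(label_table[var].median())
        codes = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
        bin_idx.append(np.nan_to_num(np.asarray(codes, dtype=float), nan=0).astype(int))
    bin_idx.append(label_table[binary_var].fillna(0).astype(int).to_numpy())
    coords = np.stack(bin_idx, axis=1)

    # merge singleton strata into the nearest stratum (Manhattan on bin coords)
    uniq, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    while np.any(counts[np.unique(inverse)] < 2) and len(np.unique(inverse)) > 1:
        sizes = np.bincount(inverse, minlength=len(uniq))
        small = np.flatnonzero((sizes > 0) & (sizes < 2))
        if small.size == 0:
            break
        s = small[0]
        others = np.flatnonzero((sizes >= 2) | ((sizes > 0) & (np.arange(len(uniq)) != s)))
        others = others[others != s]
        dist = np.abs(uniq[others] - uniq[s]).sum(axis=1)
        tgt = others[np.argmin(dist)]
        inverse[inverse == s] = tgt
        counts = np.bincount(inverse, minlength=len(uniq))

    strata = np.unique(inverse)
    counts = np.array([(inverse == s).sum() for s in strata])
    alloc = _allocate(counts, fractions)

    fold = np.empty(n, dtype=object)
    for row, s in enumerate(strata):
        members = np.flatnonzero(inverse == s)
        members = members[rng.permutation(members.size)]
        start = 0
        for j, name in enumerate(FOLDS):
            fold[members[start : start + alloc[row, j]]] = name
            start += alloc[row, j]
    return pd.DataFrame({"fold": fold, "stratum": inverse}, index=label_table.index)
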