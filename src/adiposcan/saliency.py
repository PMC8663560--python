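"""Gradients-x-input attribution and anatomical region scoring.

For a frozen network in evaluation mode, the attribution of a voxel is the
product of its input intensity with the gradient of one selected output
node with respect to that voxel.  For the binary heads only the node
matching the subject's true label is differentiated (e.g. for a female
subject, the gradient that increases the female probability); for the
regression heads the single output node is used and only positive gradient
components are kept.  The product is exactly zero wherever the input is
zero, so attribution never leaks into the background.

Region scoring mechanizes expert heatmap rating: a map "highlights" an
anatomical region when the region captures at least a configured share of
the map's strongest attribution voxels, and the report is the fraction of
maps highlighting each region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn.densenet import CLASSIFICATION_HEADS, REGRESSION_HEADS, DenseNet3D


@dataclass
class GradientMap:
    values: np.ndarray
    target: str
    mode: str  # 'label_node' for classification, 'positive' for regression


def gradient_x_input(
    net: DenseNet3D,
    volume: np.ndarray,
    target_head: str,
    true_label: int | None = None,
    positive_only_classification: bool = False,
) -> GradientMap:
    """Per-voxel attribution for one volume and one output head.

    ``volume``: (D, H, W) preprocessed and centered.  For classification
    heads ``true_label`` selects the output node; for regression heads only
    positive gradient components enter the product.
    """
    if target_head in CLASSIFICATION_HEADS:
        if true_label is None:
            raise ValueError("true_label is required for classification heads")
        node = int(true_label)
        mode = "label_node"
    elif target_head in REGRESSION_HEADS:
        node = 0
        mode = "positive"
    else:
        raise ValueError(f"unknown head {target_head!r}")

    x = volume[None].astype(np.float32)
    out = net.forward(x, train=False)
    dout = {target_head: np.zeros_like(out[target_head])}
    dout[target_head][0, node] = 1.0
    grad = net.backward(dout)[0]
    if mode == "positive":
        grad = np.clip(grad, 0.0, None)
    return GradientMap(values=(grad * volume).astype(np.float32), target=target_head, mode=mode)


def postprocess_heatmap(
    gmap: GradientMap,
    sigma: float = 2.0,
    clip_percentile: float = 99.0,
    projection_axis: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian smoothing + percentile contrast clipping + 2D mean projection.

    Returns ``(projection_2d, enhanced_3d)``.  The projection averages along
    the sagittal axis by default, producing the coronal view (vertical x
    left-right) used for display; the enhanced 3D map feeds region scoring.
    """
    v = np.abs(gmap.values.astype(np.float64))
    smoothed = gaussian_filter(v, sigma=sigma, mode="constant")
    if np.any(smoothed > 0):
        hi = np.percentile(smoothed[smoothed > 0], clip_percentile)
        if hi > 0:
            smoothed = np.clip(smoothed, 0.0, hi)
    projection = smoothed.mean(axis=projection_axis)
    return projection.astype(np.float32), smoothed.astype(np.float32)


def _highlighted(values: np.ndarray, region_masks: dict[str, np.ndarray], top_q: float, min_share: float):
    """Binary highlight call per region for one enhanced map.

    The map's top-``top_q`` attribution voxels are intersected with each
    region; the share is normalized by the attainable maximum
    ``min(top-set size, region size)`` so small anatomical regions (the
    visceral depots are <1% of the grid) can reach a full score when the
    attribution concentrates inside them.
    """
    flat = values.ravel()
    n_top = max(1, int(round(top_q * flat.size)))
    top_idx = np.argpartition(flat, -n_top)[-n_top:]
    top_mask = np.zeros(flat.size, dtype=bool)
    top_mask[top_idx] = True
    calls = {}
    for r, m in region_masks.items():
        size = int(m.sum())
        if size == 0:
            calls[r] = False
            continue
        overlap = int(np.count_nonzero(top_mask & m.ravel()))
        calls[r] = overlap / min(n_top, size) >= min_share
    return calls


def region_mean_attribution(
    maps: list[GradientMap],
    region_masks,
    sigma: float = 2.0,
) -> dict[str, float]:
    """Per-region mean voxel attribution, averaged over maps.

    Each enhanced map is normalized to unit mean over the body (union of
    region masks and nonzero attribution) so maps contribute equally; the
    statistic is the mean attribution per voxel inside each region.  This
    is the rank statistic used to ask *which* anatomical region dominates a
    label's heatmaps — discriminating where the binary highlight calls of
    ``region_fractions`` may saturate.
    """
    per_map_masks = region_masks if isinstance(region_masks, list) else [region_masks] * len(maps)
    names = list(per_map_masks[0])
    acc = {r: 0.0 for r in names}
    for gmap, masks in zip(maps, per_map_masks):
        _, enhanced = postprocess_heatmap(gmap, sigma=sigma)
        support = enhanced > 0
        norm = enhanced[support].mean() if support.any() else 1.0
        for r in names:
            m = masks[r]
            if m.any():
                acc[r] += float(enhanced[m].mean() / norm)
    n = max(len(maps), 1)
    return {r: acc[r] / n for r in names}


def region_fractions(
    maps: list[GradientMap],
    region_masks: dict[str, np.ndarray],
    top_q: float = 0.05,
    min_share: float = 0.10,
    sigma: float = 2.0,
) -> dict[str, float]:
    """Fraction of maps in which each anatomical region is highlighted.

    ``region_masks`` may be shared across maps or a list aligned with
    ``maps`` (per-subject masks).
    """
    per_map_masks: list[dict[str, np.ndarray]]
    if isinstance(region_masks, list):
        per_map_masks = region_masks
    else:
        per_map_masks = [region_masks] * len(maps)
    if len(per_map_masks) != len(maps):
        raise ValueError("region_masks list must align with maps")

    names = list(per_map_masks[0])
    counts = {r: 0 for r in names}
    for gmap, masks in zip(maps, per_map_masks):
        if masks[names[0]].shape != gmap.values.shape:
            raise ValueError("region masks are not aligned to the map grid")
        _, enhanced = postprocess_heatmap(gmap, sigma=sigma)
        calls = _highlighted(enhanced, masks, top_q, min_share)
        for r in names:
            counts[r] += int(calls[r])
    n = max(len(maps), 1)
    return {r: counts[r] / n for r in names}
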