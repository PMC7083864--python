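"""Soma localization via the modified directional ratio.

For a response stack ``r[j, l]`` the per-pixel statistic at scale ``j`` is

    min_l |r[j, l](p)|^2 / (max_l |r[j, l](p)| + eps)

computed after dividing the whole stack by its global maximum absolute
value, which makes the statistic dimensionless in [0, 1]: close to 1 inside
locally isotropic blobs (cell bodies), close to 0 on vessel-like elongated
structures.  Thresholding the per-pixel maximum over scales yields candidate
soma regions; each surviving connected component contributes one centroid
and one square region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filters import DirectionalFilterBank, DirectionalResponseStack, apply_bank

__all__ = [
    "DirectionalRatioMap",
    "DetectionResult",
    "directional_ratio",
    "directional_ratio_max",
    "detect_cells",
]

DEFAULT_DR_THRESHOLD = 0.7
DEFAULT_PATCH_SIZE = 128
DEFAULT_MIN_BLOB_AREA = 4
DEFAULT_EPS = 1e-12
#: Gaussian sigma applied to the image before the directional ratio;
#: stabilizes the orientation minimum against photon noise
DEFAULT_PRE_SMOOTH = 2.5
#: fragments of one soma sit within about a soma diameter of each other;
#: anything farther apart is treated as a distinct cell
DEFAULT_MERGE_DISTANCE = 24.0
#: responses are normalized by this percentile of their absolute values
#: (then clipped to 1) rather than the raw maximum, so one unusually sharp
#: object cannot depress the statistic everywhere else
DEFAULT_NORM_PERCENTILE = 99.95
#: candidate components must be at least this much brighter (mean, in
#: normalized units) than the image median; rejects isotropic noise lumps
#: on near-empty images, where min-max normalization stretches residual
#: noise to full range
DEFAULT_MIN_CONTRAST = 0.3


@dataclass(frozen=True)
class DirectionalRatioMap:
    values: np.ndarray
    scale: int
    border_margin: int


@dataclass(frozen=True)
class DetectionResult:
    """Centroids with their axis-aligned square ROIs.

    ROIs are half-open windows ``[top, top+size) x [left, left+size)``; they
    may extend past the image bounds, in which case the extracted patch is
    zero-padded back to full size by :meth:`extract_patch`.
    """

    centroids: list[tuple[float, float]]
    rois: list[tuple[int, int, int]]
    source_image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.centroids)

    def extract_patch(self, image: np.ndarray, index: int) -> np.ndarray:
        top, left, size = self.rois[index]
        patch = np.zeros((size, size), dtype=float)
        r0, r1 = max(top, 0), min(top + size, image.shape[0])
        c0, c1 = max(left, 0), min(left + size, image.shape[1])
        patch[r0 - top: r1 - top, c0 - left: c1 - left] = image[r0:r1, c0:c1]
        return patch


def directional_ratio(stack: DirectionalResponseStack, scale: int,
                      eps: float = DEFAULT_EPS,
                      norm_percentile: float = DEFAULT_NORM_PERCENTILE,
                      ) -> DirectionalRatioMap:
    """Directional ratio at one scale of a response stack.

    Responses at the scale are first divided by a high percentile of their
    absolute values over the image and clipped to 1, so the statistic is
    dimensionless in [0, 1] and invariant to a positive rescaling of the
    input.  ``norm_percentile=100`` recovers plain max normalization.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if not 0 <= scale < stack.n_scales:
        raise ValueError(f"scale {scale} outside bank range [0, {stack.n_scales})")
    a = np.abs(stack[scale])
    norm = float(np.percentile(a, norm_percentile))
    if norm > 0:
        a = np.minimum(a / norm, 1.0)
    mn = a.min(axis=0)
    mx = a.max(axis=0)
    values = mn * mn / (mx + eps)
    return DirectionalRatioMap(
        values=values,
        scale=scale,
        border_margin=stack.bank.half_width(scale),
    )


def directional_ratio_max(stack: DirectionalResponseStack,
                          scales: list[int] | None = None,
                          eps: float = DEFAULT_EPS,
                          norm_percentile: float = DEFAULT_NORM_PERCENTILE,
                          ) -> DirectionalRatioMap:
    """Per-pixel maximum of the per-scale directional ratio."""
    scales = list(range(stack.n_scales)) if scales is None else scales
    maps = [directional_ratio(stack, j, eps, norm_percentile) for j in scales]
    values = np.maximum.reduce([m.values for m in maps])
    return DirectionalRatioMap(
        values=values,
        scale=max(scales),
        border_margin=max(m.border_margin for m in maps),
    )


def detect_cells(
    image: np.ndarray,
    bank: DirectionalFilterBank,
    dr_threshold: float = DEFAULT_DR_THRESHOLD,
    min_blob_area: int = DEFAULT_MIN_BLOB_AREA,
    patch_size: int = DEFAULT_PATCH_SIZE,
    scales: list[int] | None = None,
    eps: float = DEFAULT_EPS,
    pre_smooth: float = DEFAULT_PRE_SMOOTH,
    merge_distance: float = DEFAULT_MERGE_DISTANCE,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
) -> DetectionResult:
    """Locate one centroid + square ROI per cell body.

    ``image`` is expected preprocessed and normalized to [0, 1].  Candidate
    components of the thresholded multiscale directional-ratio map smaller
    than ``min_blob_area`` are discarded; components whose centroids are
    closer than ``merge_distance`` are merged (area-weighted), since a
    single irregular soma can fragment into several super-threshold islands.
    """
    raw = np.asarray(image, dtype=float)
    image = ndimage.gaussian_filter(raw, pre_smooth) if pre_smooth > 0 else raw
    stack = apply_bank(image, bank)
    dr = directional_ratio_max(stack, scales=scales, eps=eps)
    mask = dr.values >= dr_threshold

    labels, n = ndimage.label(mask)
    if n == 0:
        return DetectionResult([], [], image.shape)

    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labels, index=idx)
    contrast = ndimage.mean(raw, labels, index=idx) - np.median(raw)
    keep = np.flatnonzero((areas >= min_blob_area)
                          & (contrast >= min_contrast)) + 1
    if keep.size == 0:
        return DetectionResult([], [], image.shape)
    centroids = ndimage.center_of_mass(mask, labels, index=keep)
    weights = [float(areas[i - 1]) for i in keep]

    merged = _merge_close(list(centroids), weights, merge_distance)
    merged.sort()

    rois = []
    for (r, c) in merged:
        top = int(round(r)) - patch_size // 2
        left = int(round(c)) - patch_size // 2
        rois.append((top, left, patch_size))
    return DetectionResult(merged, rois, image.shape)


def _merge_close(centroids: list[tuple[float, float]], weights: list[float],
                 min_separation: float) -> list[tuple[float, float]]:
    """Greedy agglomeration of centroids closer than ``min_separation``."""
    pts = [np.asarray(p, dtype=float) for p in centroids]
    w = list(weights)
    changed = True
    while changed and len(pts) > 1:
        changed = False
        best = None
        best_d = min_separation
        for i in range(len(pts)):
            for k in range(i + 1, len(pts)):
                d = float(np.hypot(*(pts[i] - pts[k])))
                if d < best_d:
                    best_d = d
                    best = (i, k)
        if best is not None:
            i, k = best
            total = w[i] + w[k]
            pts[i] = (pts[i] * w[i] + pts[k] * w[k]) / total
            w[i] = total
            del pts[k], w[k]
            changed = True
    return [(float(p[0]), float(p[1])) for p in pts]
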