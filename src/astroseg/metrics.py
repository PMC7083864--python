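"""Detection matching and evaluation metrics.

Sensitivity S = TP/(TP+FN), precision P = TP/(TP+FP) and Dice's
coefficient DC = 2TP/(2TP+FP+FN), at cell level (centroid matching within
a radius) or pixel level (mask overlap).  DC equals the harmonic mean
2SP/(S+P) whenever S and P are defined and positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "match_detections",
    "compute_metrics",
    "pixel_metrics",
    "weighted_average_metrics",
    "DEFAULT_MATCH_RADIUS",
]

#: default centroid-match radius in pixels (20x / 1024x1024 scale)
DEFAULT_MATCH_RADIUS = 25.0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    S: float
    P: float
    DC: float
    level: str  # "cell" | "pixel"
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "S": self.S,
            "P": self.P,
            "DC": self.DC,
            "undefined": list(self.undefined),
        }


def match_detections(
    predicted: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    radius: float = DEFAULT_MATCH_RADIUS,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one nearest-pair matching within ``radius``.

    Candidate pairs are ordered by distance (ties by prediction index,
    then truth index); each point is matched at most once.  Returns the
    counts and the list of (prediction index, truth index) pairs.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.asarray(predicted, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    pairs = []
    for i in range(pred.shape[0]):
        d = np.hypot(pred[i, 0] - tru[:, 0], pred[i, 1] - tru[:, 1])
        for j in np.flatnonzero(d <= radius):
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matching = []
    for _d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matching.append((i, j))
    tp = len(matching)
    counts = ConfusionCounts(TP=tp, FP=pred.shape[0] - tp, FN=tru.shape[0] - tp)
    return counts, matching


def compute_metrics(counts: ConfusionCounts, level: str = "cell") -> MetricsReport:
    """Report S, P, DC for the given counts.

    Ratios with a zero denominator are reported as NaN and named in
    ``undefined`` — never silently zero.  All-zero counts are a
    degenerate input and raise.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("all confusion counts are zero; metrics undefined")
    undefined = []
    if tp + fn > 0:
        s = tp / (tp + fn)
    else:
        s, undefined = math.nan, undefined + ["S"]
    if tp + fp > 0:
        p = tp / (tp + fp)
    else:
        p, undefined = math.nan, undefined + ["P"]
    if 2 * tp + fp + fn > 0:
        dc = 2 * tp / (2 * tp + fp + fn)
    else:  # pragma: no cover - unreachable given the degenerate check
        dc, undefined = math.nan, undefined + ["DC"]
    return MetricsReport(counts=counts, S=s, P=p, DC=dc, level=level,
                         undefined=tuple(undefined))


def pixel_metrics(predicted_mask: np.ndarray,
                  truth_mask: np.ndarray) -> MetricsReport:
    """Pixel-level S/P/DC between two binary masks of equal shape."""
    pred = np.asarray(predicted_mask).astype(bool)
    tru = np.asarray(truth_mask).astype(bool)
    if pred.shape != tru.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {tru.shape}")
    tp = int(np.sum(pred & tru))
    fp = int(np.sum(pred & ~tru))
    fn = int(np.sum(~pred & tru))
    return compute_metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn), level="pixel")


def weighted_average_metrics(
    reports: list[tuple[MetricsReport, float]],
) -> tuple[float, float, float]:
    """Component-wise weighted arithmetic mean of (S, P, DC).

    Weights must sum to 1 (tolerance 1e-9).
    """
    weights = [w for _, w in reports]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    s = sum(r.S * w for r, w in reports)
    p = sum(r.P * w for r, w in reports)
    dc = sum(r.DC * w for r, w in reports)
    return s, p, dc
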