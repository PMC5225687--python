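"""Contour agreement metrics: mean distance (MD), Hausdorff distance (HD)
and confusion-matrix statistics.

The distance from a point to a contour is the minimum Euclidean distance to
the contour's polygonal *segments* (not just its vertices), which makes the
metrics robust to unequal sampling densities between automatic and manual
traces; a vertex-only variant is available behind a flag for strict
vertex-set comparison.  MD averages, and HD maximises, the point-to-contour
distances symmetrically in both directions.  Millimetre outputs are pixel
distances times the pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermio import Contour, UndefinedStatisticError, ValidationError

__all__ = [
    "EvalReport",
    "ConfusionStats",
    "point_to_contour_distance",
    "mean_distance",
    "hausdorff_distance",
    "evaluate_contours",
    "confusion_stats",
]


@dataclass
class EvalReport:
    """MD and HD between an automatic and a manual contour, in mm."""

    md_mm: float
    hd_mm: float
    n_auto: int
    n_manual: int
    pitch_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.md_mm <= self.hd_mm + 1e-12):
            raise ValidationError(
                f"report violates 0 <= MD <= HD: md={self.md_mm}, "
                f"hd={self.hd_mm}")


def _segment_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each query point to the closed polygon's segments."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a                                    # (S, 2)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2[ab2 < 1e-24] = 1e-24                      # degenerate segments
    ap = points[:, None, :] - a[None, :, :]       # (P, S, 2)
    t = np.clip(np.einsum("psi,si->ps", ap, ab) / ab2, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def _vertex_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - poly[None, :, :], axis=2)
    return d.min(axis=1)


def point_to_contour_distance(a, M: Contour,
                              vertex_only: bool = False) -> float:
    """Distance (px) from point ``a`` to contour ``M``."""
    pts = np.atleast_2d(np.asarray(a, dtype=float))
    fn = _vertex_distances if vertex_only else _segment_distances
    return float(fn(pts, M.points)[0])


def mean_distance(A: Contour, M: Contour, vertex_only: bool = False) -> float:
    """Symmetric mean point-to-contour distance (px): the average of the
    mean distance from A's vertices to M and from M's vertices to A."""
    fn = _vertex_distances if vertex_only else _segment_distances
    return 0.5 * (float(fn(A.points, M.points).mean())
                  + float(fn(M.points, A.points).mean()))


def hausdorff_distance(A: Contour, M: Contour,
                       vertex_only: bool = False) -> float:
    """Symmetric Hausdorff distance (px): the worst point-to-contour
    distance in either direction."""
    fn = _vertex_distances if vertex_only else _segment_distances
    return max(float(fn(A.points, M.points).max()),
               float(fn(M.points, A.points).max()))


def evaluate_contours(auto: Contour, manual: Contour,
                      pitch_mm: float = 1.0,
                      vertex_only: bool = False) -> EvalReport:
    """MD/HD report between an automatic and a manual contour."""
    if not pitch_mm > 0:
        raise ValidationError("pitch_mm must be > 0")
    md = mean_distance(auto, manual, vertex_only)
    hd = hausdorff_distance(auto, manual, vertex_only)
    return EvalReport(md_mm=md * pitch_mm, hd_mm=hd * pitch_mm,
                      n_auto=len(auto), n_manual=len(manual),
                      pitch_mm=pitch_mm)


@dataclass
class ConfusionStats:
    sensitivity: float
    specificity: float
    accuracy: float


def confusion_stats(tp: int, fp: int, tn: int, fn: int) -> ConfusionStats:
    """Sensitivity ``tp/(tp+fn)``, specificity ``tn/(tn+fp)`` and accuracy
    ``(tp+tn)/total`` as fractions; a zero denominator raises an error
    naming the statistic."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if tp + fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: tp + fn = 0")
    if tn + fp == 0:
        raise UndefinedStatisticError("specificity undefined: tn + fp = 0")
    total = tp + fp + tn + fn
    return ConfusionStats(sensitivity=tp / (tp + fn),
                          specificity=tn / (tn + fp),
                          accuracy=(tp + tn) / total)
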