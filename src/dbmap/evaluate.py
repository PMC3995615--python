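"""Evaluation of cluster localization: ROC/AUC, high-risk-region extraction,
compactness ("reasonable geographic extent") and the difference-in-distances
(DiD) statistic.

The simulated mixture dichotomizes risk: grid points inside the cluster
square carry elevated risk, all others do not.  A good map gives high scores
inside and low scores outside, which the AUC summarizes over all thresholds.
For aggregated data the located high-risk area is additionally compared
against the cluster focus and the "average centroid" — the case-weighted
mean of the centroids that received the cluster's cases — because
aggregation can only place risk at centroid locations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from sklearn.metrics import roc_auc_score

from .aggregation import AggregationScheme
from .mapping import PaletteCalibration, RiskMap
from .regions import EvalGrid

__all__ = [
    "label_grid",
    "roc_auc",
    "extract_high_region",
    "reasonable_extent",
    "average_centroid",
    "did_metric",
    "HULL_FILL_TOLERANCE",
    "HULL_DIAMETER_FACTOR",
]

# compactness thresholds: at most this many grid points may separate the
# high-score set from its convex hull (~1% of a full-resolution disk grid),
# and the hull may span at most this multiple of the aggregation side length
HULL_FILL_TOLERANCE = 80
HULL_DIAMETER_FACTOR = 1.75


def label_grid(grid: EvalGrid, focus, diameter: float) -> np.ndarray:
    """Boolean labels: True iff a grid point lies in the closed axis-aligned
    square of side ``diameter`` centered at ``focus``."""
    fx, fy = np.asarray(focus, dtype=float).ravel()
    h = diameter / 2.0
    pts = grid.points
    return (np.abs(pts[:, 0] - fx) <= h) & (np.abs(pts[:, 1] - fy) <= h)


def roc_auc(scores, labels) -> float:
    """AUC of scores against binary labels (rank/Mann-Whitney formulation,
    ties shared).  Raises ``ValueError`` when only one class is present."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def extract_high_region(
    risk_map: RiskMap, palette: PaletteCalibration, fraction: float = 0.95
) -> np.ndarray:
    """Indices of grid points in the palette's highest color band.

    "High" means at or above 95% of the palette's value scale, whose range is
    calibrated from the pooled null scores.  (The pooled 0.95 probability
    quantile would instead flag ~5% of all grid points on every map — a
    scattered set whose convex hull spans the region, so no iteration could
    ever locate a compact high-risk area.)
    """
    return np.nonzero(risk_map.scores >= palette.range_threshold(fraction))[0]


def _hull_diameter(points: np.ndarray) -> float:
    d = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((d**2).sum(axis=-1)).max())


def reasonable_extent(subset, grid: EvalGrid, side_length: float) -> bool:
    """Is the located high-score region compact at the aggregation scale?

    True iff (a) at most ``HULL_FILL_TOLERANCE`` grid points lie inside the
    subset's convex hull without belonging to the subset, and (b) the hull's
    diameter (largest pairwise vertex distance) is at most
    ``HULL_DIAMETER_FACTOR`` times ``side_length``.  Degenerate subsets
    (fewer than 3 points, or collinear) have hull equal to the subset itself,
    so only the diameter criterion can fail.
    """
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        raise ValueError("high-score subset is empty")
    if side_length <= 0:
        raise ValueError("side_length must be positive")
    pts = grid.points[subset]
    try:
        hull = ConvexHull(pts)
        vertices = pts[hull.vertices]
        inside = Delaunay(vertices).find_simplex(grid.points) >= 0
        missing = int(np.count_nonzero(inside)) - len(subset)
        diameter = _hull_diameter(vertices)
    except QhullError:  # < 3 points or collinear: hull degenerates to the set
        missing = 0
        diameter = _hull_diameter(pts) if len(pts) > 1 else 0.0
    return missing <= HULL_FILL_TOLERANCE and diameter <= HULL_DIAMETER_FACTOR * side_length


def average_centroid(cluster_points, scheme: AggregationScheme) -> np.ndarray:
    """Case-weighted mean of the centroids receiving the cluster's cases.

    ``cluster_points`` are the simulated case locations that originated from
    the cluster component; each contributes its cell's centroid, weighted by
    the cell's share of those points.
    """
    pts = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    if len(pts) == 0:
        raise ValueError("cluster point list is empty")
    idx = scheme.cell_of(pts)
    if np.any(idx < 0):
        raise ValueError("cluster point outside every aggregation cell")
    counts = np.bincount(idx, minlength=scheme.m).astype(float)
    w = counts / counts.sum()
    return (scheme.centroids * w[:, None]).sum(axis=0)


def did_metric(subset, grid: EvalGrid, focus, avg_centroid) -> float:
    """Difference in distances from the located area's center.

    The center is the arithmetic mean of the subset's grid points; the value
    is ``||center - focus|| - ||center - avg_centroid||``, positive when the
    located area sits closer to the average centroid than to the true focus.
    """
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        raise ValueError("high-score subset is empty")
    center = grid.points[subset].mean(axis=0)
    focus = np.asarray(focus, dtype=float).ravel()
    avg = np.asarray(avg_centroid, dtype=float).ravel()
    return float(np.hypot(*(center - focus)) - np.hypot(*(center - avg)))
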