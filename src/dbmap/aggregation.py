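"""Regular-grid aggregation of point data over a disk region.

Aggregation reassigns each case location to the centroid of the grid square
containing it, emulating data released only at an administrative-unit
level.  Centroids are slightly off-center (seeded jitter) so that the
aggregated geometry is not perfectly regular, and the continuous reference
distribution is discretized onto the same centroids with cell masses equal
to the reference probability of each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .mapping import CaseSet
from .reference import DiscreteReference, UniformDiskReference
from .regions import StudyRegion

__all__ = ["AggregationScheme", "build_scheme", "aggregate_cases", "discretize_reference"]

JITTER_FRACTION = 0.15  # centroid offset amplitude, as a fraction of cell side


@dataclass(frozen=True)
class AggregationScheme:
    """Partition of a disk region into axis-aligned lattice squares.

    Only cells whose intersection with the open disk has positive area are
    kept; ``cells`` holds lower-left corners, ``centroids`` one off-center
    representative point per cell (inside both the cell and the region).
    Cell membership is half-open (``[lo, lo+side)`` in each axis) so every
    interior point belongs to exactly one cell.
    """

    region: StudyRegion
    side_length: float
    squares_across: int
    cells: np.ndarray = field(repr=False)          # (m, 2) lower-left corners
    centroids: np.ndarray = field(repr=False)      # (m, 2)
    _index: np.ndarray = field(repr=False)         # (sa, sa) lattice -> cell id or -1

    @property
    def m(self) -> int:
        return len(self.cells)

    def cell_of(self, points) -> np.ndarray:
        """Cell index for each point; -1 for points outside every kept cell."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cx, cy = self.region.center
        R = self.region.radius
        ix = np.floor((pts[:, 0] - (cx - R)) / self.side_length).astype(int)
        iy = np.floor((pts[:, 1] - (cy - R)) / self.side_length).astype(int)
        ok = (ix >= 0) & (ix < self.squares_across) & (iy >= 0) & (iy < self.squares_across)
        out = np.full(len(pts), -1, dtype=int)
        out[ok] = self._index[ix[ok], iy[ok]]
        return out


def build_scheme(
    region: StudyRegion, squares_across: int, jitter_seed=None
) -> AggregationScheme:
    """Lay a ``squares_across x squares_across`` lattice of squares over the
    region's bounding square and keep the cells overlapping the open disk.

    The cell side is ``2 * radius / squares_across``.  Each centroid is the
    cell center displaced by a seeded uniform offset up to ``+/-0.15 * side``
    per axis, re-drawn until it lands inside both the cell and the region;
    boundary cells whose center lies outside the disk fall back to a uniform
    draw inside the cell-disk intersection.
    """
    if squares_across < 1:
        raise ValueError("squares_across must be >= 1")
    rng = (
        jitter_seed
        if isinstance(jitter_seed, np.random.Generator)
        else np.random.default_rng(jitter_seed)
    )
    cx, cy = region.center
    R = region.radius
    side = 2.0 * R / squares_across
    lows = np.array([cx - R, cy - R])

    cells = []
    lattice_index = np.full((squares_across, squares_across), -1, dtype=int)
    for ix in range(squares_across):
        for iy in range(squares_across):
            lo = lows + side * np.array([ix, iy])
            nearest = np.clip([cx, cy], lo, lo + side)
            if (nearest[0] - cx) ** 2 + (nearest[1] - cy) ** 2 < R**2:
                lattice_index[ix, iy] = len(cells)
                cells.append(lo)
    cells = np.asarray(cells)

    centroids = np.empty_like(cells)
    for k, lo in enumerate(cells):
        center = lo + side / 2.0
        placed = False
        for _ in range(200):
            cand = center + rng.uniform(-JITTER_FRACTION * side, JITTER_FRACTION * side, 2)
            inside_cell = np.all(cand >= lo) and np.all(cand < lo + side)
            if inside_cell and region.contains(cand)[0]:
                centroids[k] = cand
                placed = True
                break
        while not placed:  # cell center outside the disk: sample cell-disk overlap
            cand = lo + rng.uniform(0.0, side, 2)
            if region.contains(cand)[0]:
                centroids[k] = cand
                placed = True
    return AggregationScheme(
        region=region,
        side_length=side,
        squares_across=squares_across,
        cells=cells,
        centroids=centroids,
        _index=lattice_index,
    )


def aggregate_cases(points, scheme: AggregationScheme) -> CaseSet:
    """Reassign case locations to the centroid of their grid square,
    returning per-unit counts (total conserved)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = scheme.cell_of(pts)
    if np.any(idx < 0):
        bad = pts[idx < 0][0]
        raise ValueError(f"point {tuple(bad)} lies outside every aggregation cell")
    counts = np.bincount(idx, minlength=scheme.m).astype(float)
    return CaseSet.from_counts(scheme.centroids, counts)


def discretize_reference(
    reference: UniformDiskReference,
    scheme: AggregationScheme,
    mc_samples: int = 4096,
    seed: int = 0,
) -> DiscreteReference:
    """Project a uniform-disk reference onto a scheme's centroids.

    Each cell receives mass proportional to the area of its intersection
    with the disk: exact for cells fully inside the disk, seeded quasi-random
    (Halton) estimates for boundary cells; masses are renormalized to sum
    to 1.
    """
    if not isinstance(reference, UniformDiskReference):
        raise TypeError("only a uniform-disk reference can be discretized")
    region = scheme.region
    cx, cy = region.center
    R = region.radius
    side = scheme.side_length
    u = qmc.Halton(d=2, seed=seed).random(mc_samples)
    masses = np.empty(scheme.m)
    for k, lo in enumerate(scheme.cells):
        corners = lo + side * np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        far = np.hypot(corners[:, 0] - cx, corners[:, 1] - cy).max()
        if far <= R:
            masses[k] = side * side
        else:
            p = lo + side * u
            frac = np.mean((p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 < R**2)
            masses[k] = side * side * frac
    masses /= masses.sum()
    return DiscreteReference(scheme.centroids, masses)
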