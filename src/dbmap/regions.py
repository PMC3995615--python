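"""Study regions, evaluation grids and projection circles.

The mapping method scores a finite lattice of grid points laid over a disk-
shaped study region, using projections onto distances from a set of fixed
points placed on a circle circumscribing the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StudyRegion", "EvalGrid", "ProjectionSet", "make_eval_grid", "make_circle_points"]


@dataclass(frozen=True)
class StudyRegion:
    """A disk-shaped study region.

    ``kind`` records how the disk was obtained: the canonical unit disk used
    in simulations, or a disk circumscribing an observed point set (used for
    centroid-table data, where only a covering region is needed).
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.0
    kind: str = "unit-disk"

    def __post_init__(self):
        if not np.isfinite(self.center).all():
            raise ValueError("region center must be finite")
        if not self.radius > 0:
            raise ValueError("region radius must be positive")

    @classmethod
    def unit_disk(cls) -> "StudyRegion":
        return cls()

    @classmethod
    def from_points(cls, points, pad: float = 0.05) -> "StudyRegion":
        """Disk circumscribing ``points``: centered at the bounding-box center
        with radius the maximum point distance, inflated by ``pad`` (relative)."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
            raise ValueError("points must be a non-empty (n, 2) array")
        cx = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
        cy = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
        r = float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).max())
        if r == 0.0:
            r = 1.0
        return cls(center=(cx, cy), radius=r * (1.0 + pad), kind="bounding-box-of-point-set")

    def contains(self, points) -> np.ndarray:
        """Strict-interior membership test, vectorized over an (n, 2) array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = (pts[:, 0] - self.center[0]) ** 2 + (pts[:, 1] - self.center[1]) ** 2
        return d2 < self.radius**2


@dataclass(frozen=True)
class EvalGrid:
    """Ordered evaluation lattice ``{y_1, ..., y_r}`` inside a study region."""

    points: np.ndarray
    spacing: float
    provenance: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
            raise ValueError("grid must contain at least one point")
        object.__setattr__(self, "points", pts)

    @property
    def r(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ProjectionSet:
    """``N`` fixed points on a circle around the region, one per projection."""

    center: tuple[float, float]
    circle_radius: float
    points: np.ndarray = field(repr=False)

    @property
    def N(self) -> int:
        return len(self.points)


def make_eval_grid(region: StudyRegion, lattice_count: int) -> EvalGrid:
    """Cell centers of a ``lattice_count x lattice_count`` lattice over the
    region's bounding square, restricted to the strict interior of the region.

    The achieved number of grid points ``r`` approaches ``pi/4 *
    lattice_count**2`` for a disk; the exact value depends on this lattice
    convention and is recorded in the grid's provenance.
    """
    if lattice_count < 1:
        raise ValueError("lattice_count must be >= 1")
    cx, cy = region.center
    R = region.radius
    coords = cx - R + (np.arange(lattice_count) + 0.5) * (2.0 * R / lattice_count)
    coords_y = cy - R + (np.arange(lattice_count) + 0.5) * (2.0 * R / lattice_count)
    X, Y = np.meshgrid(coords, coords_y, indexing="xy")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    # stable row-major order: y varies slowest, x fastest
    pts = pts[np.lexsort((pts[:, 0], pts[:, 1]))]
    inside = region.contains(pts)
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("lattice too coarse: no grid point falls inside the region")
    spacing = 2.0 * R / lattice_count
    prov = (
        f"cell centers of {lattice_count}x{lattice_count} lattice over bounding square, "
        f"strict interior, r={len(pts)}"
    )
    return EvalGrid(points=pts, spacing=spacing, provenance=prov)


def make_circle_points(region: StudyRegion, N: int, radius_factor: float = 1.0) -> ProjectionSet:
    """``N`` equally spaced points (angles ``2*pi*k/N`` from angle 0) on the
    circle of radius ``radius_factor * region.radius`` about the region center."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if radius_factor < 1.0:
        raise ValueError("radius_factor must be >= 1 so the circle circumscribes the region")
    rad = radius_factor * region.radius
    ang = 2.0 * np.pi * np.arange(N) / N
    pts = np.column_stack(
        [region.center[0] + rad * np.cos(ang), region.center[1] + rad * np.sin(ang)]
    )
    return ProjectionSet(center=region.center, circle_radius=rad, points=pts)
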