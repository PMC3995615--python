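"""One-dimensional distance distributions.

Each projection point ``c`` turns a planar distribution into a distribution
of distances ``d = ||c - X||``.  Two concrete CDF families cover every case
handled by the package:

* :class:`UniformDiskDistanceCDF` — the analytic CDF of the distance from
  ``c`` to a uniform draw on a disk, via the disk-disk lens area;
* :class:`StepCDF` — a weighted step CDF, used both for empirical
  distributions of observed case distances and for discrete (centroid-mass)
  reference distributions.

All evaluation and inversion is vectorized, which is what makes whole-map
computation cheap: scoring a map needs these CDFs at every grid point for
every projection.
"""

from __future__ import annotations

import abc

import numpy as np

from .geometry import disk_overlap_area
from .regions import StudyRegion

__all__ = [
    "DistanceCDF",
    "StepCDF",
    "UniformDiskDistanceCDF",
    "uniform_disk_distance_cdf",
    "discrete_distance_cdf",
]

class DistanceCDF(abc.ABC):
    """A cumulative distribution function of a non-negative distance.

    ``evaluate`` and ``inverse`` accept scalars or arrays.  ``support`` is the
    interval ``[d_min, d_max]`` outside of which the CDF is constant 0 / 1.
    """

    support: tuple[float, float]

    @abc.abstractmethod
    def evaluate(self, d):
        """CDF value(s) at distance(s) ``d``."""

    @abc.abstractmethod
    def inverse(self, q):
        """(Generalized) quantile(s) at probability level(s) ``q``."""


class StepCDF(DistanceCDF):
    """Right-continuous step CDF with jumps at ``values`` of size ``weights``.

    Ties in ``values`` are merged into a single jump of combined weight.
    Weights must be non-negative and sum to 1 (within ``tol``).  The inverse
    is the left-continuous generalized quantile.
    """

    def __init__(self, values, weights, *, tol: float = 1e-9):
        values = np.asarray(values, dtype=float).ravel()
        weights = np.asarray(weights, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("step CDF needs at least one support point")
        if values.shape != weights.shape:
            raise ValueError("values and weights must have equal length")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if abs(total - 1.0) > tol:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        keep = weights > 0
        values, weights = values[keep], weights[keep]
        uniq, inv = np.unique(values, return_inverse=True)
        w = np.bincount(inv, weights=weights, minlength=len(uniq))
        self.values = uniq
        self.weights = w
        # padded cumulative-mass table for O(log m) queries
        self._cum = np.concatenate([[0.0], np.cumsum(w)])
        self._cum[-1] = 1.0
        self.support = (float(uniq[0]), float(uniq[-1]))

    def evaluate(self, d):
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(self.values, d, side="right")
        out = self._cum[idx]
        return out if out.ndim else float(out)

    def inverse(self, q):
        q = np.asarray(q, dtype=float)
        qq = np.clip(q, 0.0, 1.0)
        idx = np.searchsorted(self._cum[1:], qq, side="left")
        idx = np.minimum(idx, len(self.values) - 1)
        out = self.values[idx]
        return out if out.ndim else float(out)


class UniformDiskDistanceCDF(DistanceCDF):
    """CDF of ``||c - X||`` for ``X`` uniform on a disk.

    ``F(d)`` is the fraction of the disk's area covered by the disk of radius
    ``d`` around ``c`` — the two-disk lens area divided by the region area.
    The inverse has no closed form and is computed by vectorized bisection to
    ~1e-15 absolute tolerance.
    """

    def __init__(self, c, region: StudyRegion | None = None):
        region = region or StudyRegion.unit_disk()
        c = np.asarray(c, dtype=float).ravel()
        if c.shape != (2,):
            raise ValueError("projection point must be a 2-vector")
        self.c = c
        self.region = region
        self._scale = region.radius
        self._R = float(np.hypot(c[0] - region.center[0], c[1] - region.center[1])) / region.radius
        d_min = max(self._R - 1.0, 0.0) * self._scale
        d_max = (self._R + 1.0) * self._scale
        self.support = (d_min, d_max)

    def evaluate(self, d):
        d = np.asarray(d, dtype=float)
        val = disk_overlap_area(self._R, np.maximum(d, 0.0) / self._scale) / np.pi
        out = np.clip(val, 0.0, 1.0)
        return out if np.ndim(out) else float(out)

    def inverse(self, q, *, iterations: int = 60):
        q = np.asarray(q, dtype=float)
        qq = np.atleast_1d(np.clip(q, 0.0, 1.0))
        lo = np.full(qq.shape, self.support[0])
        hi = np.full(qq.shape, self.support[1])
        for _ in range(iterations):
            mid = 0.5 * (lo + hi)
            below = np.atleast_1d(self.evaluate(mid)) < qq
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out = 0.5 * (lo + hi)
        return out.reshape(q.shape) if q.ndim else float(out[0])


def uniform_disk_distance_cdf(c, region: StudyRegion | None = None) -> UniformDiskDistanceCDF:
    """Distance CDF from point ``c`` under the uniform distribution on the
    (unit) disk region."""
    return UniformDiskDistanceCDF(c, region)


def discrete_distance_cdf(c, centroids, masses) -> StepCDF:
    """Distance CDF from ``c`` under a discrete centroid-mass distribution."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.size == 0:
        raise ValueError("centroid list must be non-empty")
    c = np.asarray(c, dtype=float).ravel()
    d = np.hypot(centroids[:, 0] - c[0], centroids[:, 1] - c[1])
    return StepCDF(d, masses)
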