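"""Reference ("expected") spatial distributions.

The map scores observed case distances against the distances expected under
a reference population: either the uniform distribution on the disk region
(simulation setting) or a discrete mass function on aggregation-unit
centroids (population-at-risk tables, discretized references).
"""

from __future__ import annotations

import abc

import numpy as np

from .cdf import DistanceCDF, StepCDF, UniformDiskDistanceCDF
from .regions import StudyRegion

__all__ = ["ReferenceModel", "UniformDiskReference", "DiscreteReference"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class ReferenceModel(abc.ABC):
    """Expected spatial distribution ``f0`` of case locations."""

    kind: str

    @abc.abstractmethod
    def distance_cdf(self, c) -> DistanceCDF:
        """CDF of ``||c - X||`` for ``X ~ f0``."""

    @abc.abstractmethod
    def sample(self, n: int, seed=None) -> np.ndarray:
        """``n`` iid draws from ``f0`` as an ``(n, 2)`` array; reproducible
        given ``seed`` (an int or a ``numpy.random.Generator``)."""


class UniformDiskReference(ReferenceModel):
    """Uniform distribution on a disk region."""

    kind = "continuous-uniform-disk"

    def __init__(self, region: StudyRegion | None = None):
        self.region = region or StudyRegion.unit_disk()

    def distance_cdf(self, c) -> UniformDiskDistanceCDF:
        return UniformDiskDistanceCDF(c, self.region)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        cx, cy = self.region.center
        R = self.region.radius
        out = np.empty((n, 2), dtype=float)
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = rng.uniform(-R, R, size=(m, 2))
            cand = cand[cand[:, 0] ** 2 + cand[:, 1] ** 2 < R**2]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take] + (cx, cy)
            filled += take
        return out


class DiscreteReference(ReferenceModel):
    """Discrete distribution placing mass on aggregation-unit centroids."""

    kind = "discrete-centroid-mass"

    def __init__(self, centroids, masses, unit_ids=None, *, tol: float = 1e-12):
        centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
        masses = np.asarray(masses, dtype=float).ravel()
        if len(centroids) != len(masses) or len(masses) == 0:
            raise ValueError("centroids and masses must be equal-length and non-empty")
        if np.any(masses < 0):
            raise ValueError("masses must be non-negative")
        if abs(masses.sum() - 1.0) > tol:
            raise ValueError("masses must sum to 1")
        self.centroids = centroids
        self.masses = masses
        self.unit_ids = (
            np.arange(len(masses)) if unit_ids is None else np.asarray(unit_ids)
        )

    @property
    def m(self) -> int:
        return len(self.masses)

    def distance_cdf(self, c) -> StepCDF:
        c = np.asarray(c, dtype=float).ravel()
        d = np.hypot(self.centroids[:, 0] - c[0], self.centroids[:, 1] - c[1])
        return StepCDF(d, self.masses, tol=1e-9)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        idx = rng.choice(self.m, size=n, p=self.masses / self.masses.sum())
        return self.centroids[idx]

    def sample_counts(self, n: int, seed=None) -> np.ndarray:
        """Multinomial unit counts for ``n`` draws — equivalent to ``sample``
        followed by per-centroid tallying, but cheaper for map resampling."""
        rng = _as_rng(seed)
        return rng.multinomial(n, self.masses / self.masses.sum()).astype(float)
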