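"""Distance-based mapping (DBM) of disease risk.

For each of ``N`` projection points ``c_i`` on a circle around the study
region, the observed cases induce an empirical CDF ``Fhat_i`` of distances
``||c_i - X_j||`` and the reference population induces an expected CDF
``F0_i``.  At an evaluation point ``y``, projection ``i`` contributes the difference
between the observed and expected probability content of an adaptive band
around ``t = ||c_i - y||``:

    gamma_i(y) = int_lo^hi dFhat_i - int_lo^hi dF0_i
               = [Fhat_i(hi) - Fhat_i(lo)] - [F0_i(hi) - F0_i(lo)],

where ``[lo, hi]`` is the reference-probability band of content ``p0``
centered (in probability) at ``t`` — quantiles of ``F0_i`` at
``F0_i(t) -/+ p0/2``, clipped at the support edges.  The map score is the
average over projections,

    Gamma(y) = (1/N) * sum_i gamma_i(y),

which has expectation 0 everywhere when observed equals expected (a
"flat" map) and is positive where case distances concentrate around those
of ``y`` more than the reference predicts.  The band acts as an adaptive
(quantile-width) smoothing window, so ``gamma_i`` estimates a local excess
of case mass on the projection's distance scale.

The smoothing parameter ``p0`` is shared by all projections so that each
plays a comparable role; clipping at a support edge shortens the band
rather than shifting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cdf import DistanceCDF, StepCDF
from .reference import DiscreteReference, ReferenceModel
from .regions import EvalGrid, ProjectionSet

__all__ = [
    "CaseSet",
    "RiskMap",
    "PaletteCalibration",
    "empirical_distance_cdf",
    "band_limits",
    "gamma_projection",
    "prepare_projection_contexts",
    "compute_map",
    "calibrate_palette",
]

logger = logging.getLogger(__name__)

DEFAULT_N = 20
DEFAULT_P0 = 0.1
PALETTE_LEVELS = np.append(np.round(np.arange(0.05, 0.951, 0.05), 2), 0.99)


@dataclass(frozen=True)
class CaseSet:
    """Observed cases, either exact planar locations or centroid counts.

    Continuous data carry one row per case in ``points``; discrete data carry
    one row per aggregation unit (``centroids``, real-valued ``counts`` — the
    total need not be an integer, as happens when a case's unit is known only
    up to a few neighboring units and its count is dispersed among them).
    """

    kind: str
    points: np.ndarray | None = None
    centroids: np.ndarray | None = None
    counts: np.ndarray | None = None
    unit_ids: np.ndarray | None = None

    @classmethod
    def from_points(cls, points) -> "CaseSet":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != 2 or len(pts) == 0:
            raise ValueError("continuous cases must be a non-empty (n, 2) array")
        return cls(kind="continuous", points=pts)

    @classmethod
    def from_counts(cls, centroids, counts, unit_ids=None) -> "CaseSet":
        cen = np.atleast_2d(np.asarray(centroids, dtype=float))
        cnt = np.asarray(counts, dtype=float).ravel()
        if len(cen) != len(cnt) or len(cnt) == 0:
            raise ValueError("centroids and counts must be equal-length and non-empty")
        if np.any(cnt < 0):
            raise ValueError("counts must be non-negative")
        if cnt.sum() <= 0:
            raise ValueError("total case count must be positive")
        ids = np.arange(len(cnt)) if unit_ids is None else np.asarray(unit_ids)
        return cls(kind="discrete", centroids=cen, counts=cnt, unit_ids=ids)

    @property
    def n(self) -> float:
        """Total number of cases (real-valued for dispersed counts)."""
        if self.kind == "continuous":
            return float(len(self.points))
        return float(self.counts.sum())

    def distance_weights(self, c) -> tuple[np.ndarray, np.ndarray]:
        """Distances from ``c`` to each case (or occupied centroid) with the
        probability weight each carries."""
        c = np.asarray(c, dtype=float).ravel()
        if self.kind == "continuous":
            d = np.hypot(self.points[:, 0] - c[0], self.points[:, 1] - c[1])
            w = np.full(len(d), 1.0 / len(d))
            return d, w
        occ = self.counts > 0
        cen = self.centroids[occ]
        d = np.hypot(cen[:, 0] - c[0], cen[:, 1] - c[1])
        return d, self.counts[occ] / self.counts.sum()


@dataclass(frozen=True)
class RiskMap:
    """Scores ``Gamma(y_j)`` on an evaluation grid."""

    grid: EvalGrid
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (self.grid.r,):
            raise ValueError("scores must be one value per grid point")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class PaletteCalibration:
    """Null color-scale thresholds from reference resampling.

    ``B`` datasets of the observed size are resampled from the reference,
    mapped, and the pooled scores' empirical quantiles become the palette
    breaks; a map score above the 0.95 break is "high" relative to the null.
    """

    levels: np.ndarray
    thresholds: np.ndarray
    B: int
    n_resample: float
    null_min: float = 0.0
    null_max: float = 0.0
    seed: object = None

    def threshold(self, level: float) -> float:
        """Pooled null quantile at probability ``level``."""
        idx = np.where(np.isclose(self.levels, level))[0]
        if len(idx) == 0:
            raise KeyError(f"no calibrated level {level}; available: {self.levels}")
        return float(self.thresholds[idx[0]])

    def range_threshold(self, fraction: float = 0.95) -> float:
        """Score at ``fraction`` of the palette's value scale, which spans the
        pooled null score range.  The top of the scale is the most extreme
        score seen under the null, so exceeding ``range_threshold(0.95)``
        places a grid point in the palette's highest color band — a far
        stricter notion of "high" than the 0.95 probability quantile."""
        return float(self.null_min + fraction * (self.null_max - self.null_min))


def empirical_distance_cdf(cases: CaseSet, c) -> StepCDF:
    """Step CDF of case distances to ``c`` (weights ``1/n`` per case, or
    ``count/n`` per centroid for discrete data; tied distances merge)."""
    d, w = cases.distance_weights(c)
    return StepCDF(d, w)


def band_limits(F0: DistanceCDF, t, p0: float):
    """Reference band ``[lo, hi]`` of probability content ``p0`` centered (in
    probability) at ``t``: quantiles of ``F0`` at ``F0(t) -/+ p0/2``, clipped
    at 0 and 1.  Vectorized over ``t``."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if F0.support[1] <= F0.support[0]:
        raise ValueError("degenerate reference support")
    q = F0.evaluate(t)
    lo = F0.inverse(np.maximum(np.asarray(q) - p0 / 2.0, 0.0))
    hi = F0.inverse(np.minimum(np.asarray(q) + p0 / 2.0, 1.0))
    return lo, hi


def gamma_projection(y, c, Fhat: DistanceCDF, F0: DistanceCDF, p0: float) -> float:
    """One projection's contribution at evaluation point ``y``: the observed
    minus expected probability content of the ``p0``-band around
    ``t = ||c - y||``."""
    y = np.asarray(y, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    t = float(np.hypot(c[0] - y[0], c[1] - y[1]))
    lo, hi = band_limits(F0, t, p0)
    width = float(hi) - float(lo)
    if width <= 0.0:
        logger.warning("degenerate band at t=%.6g (lo=hi=%.6g); gamma set to 0", t, lo)
        return 0.0
    obs = float(Fhat.evaluate(hi)) - float(Fhat.evaluate(lo))
    exp = float(F0.evaluate(hi)) - float(F0.evaluate(lo))
    return obs - exp


@dataclass(frozen=True)
class _ProjectionContext:
    """Per-projection quantities that depend only on the reference, the grid
    and ``p0`` — precomputed once and reused across maps of many datasets."""

    c: np.ndarray
    F0: DistanceCDF
    lo: np.ndarray
    hi: np.ndarray
    width: np.ndarray
    ref_mass: np.ndarray  # F0(hi) - F0(lo): expected band content per grid point


def prepare_projection_contexts(
    reference: ReferenceModel,
    projections: ProjectionSet,
    grid: EvalGrid,
    p0: float = DEFAULT_P0,
) -> list[_ProjectionContext]:
    """Precompute, for every projection point, the band limits and expected
    band contents at every grid point."""
    contexts = []
    for c in projections.points:
        F0 = reference.distance_cdf(c)
        t = np.hypot(grid.points[:, 0] - c[0], grid.points[:, 1] - c[1])
        lo, hi = band_limits(F0, t, p0)
        width = hi - lo
        n_clipped = int(np.count_nonzero(width <= 0))
        if n_clipped:
            logger.debug(
                "projection at %s: %d grid points with degenerate band", c, n_clipped
            )
        ref_mass = np.asarray(F0.evaluate(hi) - F0.evaluate(lo), dtype=float)
        contexts.append(
            _ProjectionContext(c=c, F0=F0, lo=lo, hi=hi, width=width, ref_mass=ref_mass)
        )
    return contexts


def compute_map(
    cases: CaseSet,
    reference: ReferenceModel,
    projections: ProjectionSet,
    grid: EvalGrid,
    p0: float = DEFAULT_P0,
    *,
    contexts: list[_ProjectionContext] | None = None,
) -> RiskMap:
    """Compute the DBM score surface ``Gamma`` on the evaluation grid.

    ``contexts`` (from :func:`prepare_projection_contexts`) may be supplied
    to reuse the reference-side precomputation across many case sets drawn
    against the same reference/grid/projections.
    """
    if contexts is None:
        contexts = prepare_projection_contexts(reference, projections, grid, p0)
    scores = np.zeros(grid.r)
    for ctx in contexts:
        Fhat = empirical_distance_cdf(cases, ctx.c)
        obs_mass = np.asarray(Fhat.evaluate(ctx.hi) - Fhat.evaluate(ctx.lo), dtype=float)
        ok = ctx.width > 0
        gam = np.zeros(grid.r)
        gam[ok] = obs_mass[ok] - ctx.ref_mass[ok]
        scores += gam
    scores /= len(contexts)
    return RiskMap(
        grid=grid,
        scores=scores,
        params={"N": projections.N, "p0": p0, "comparator": "difference"},
    )


def calibrate_palette(
    reference: ReferenceModel,
    n_cases: float,
    projections: ProjectionSet,
    grid: EvalGrid,
    p0: float = DEFAULT_P0,
    B: int = 99,
    seed=None,
    *,
    contexts: list[_ProjectionContext] | None = None,
) -> PaletteCalibration:
    """Null color-scale calibration by resampling from the reference.

    Draws ``B`` datasets of ``round(n_cases)`` cases from ``reference``,
    computes each risk map, pools the ``B * r`` scores and returns their
    empirical quantiles at levels 0.05, 0.10, ..., 0.95 and 0.99.
    """
    if B < 19:
        raise ValueError("B must be >= 19 for a meaningful 95% threshold")
    rng = np.random.default_rng(seed)
    if contexts is None:
        contexts = prepare_projection_contexts(reference, projections, grid, p0)
    n = int(round(n_cases))
    pooled = np.empty((B, grid.r))
    for b in range(B):
        if isinstance(reference, DiscreteReference):
            cases = CaseSet.from_counts(
                reference.centroids, reference.sample_counts(n, rng)
            )
        else:
            cases = CaseSet.from_points(reference.sample(n, rng))
        pooled[b] = compute_map(
            cases, reference, projections, grid, p0, contexts=contexts
        ).scores
    thresholds = np.quantile(pooled.ravel(), PALETTE_LEVELS)
    return PaletteCalibration(
        levels=PALETTE_LEVELS.copy(),
        thresholds=thresholds,
        B=B,
        n_resample=float(n),
        null_min=float(pooled.min()),
        null_max=float(pooled.max()),
        seed=seed,
    )
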