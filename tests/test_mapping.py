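import numpy as np
import pytest

from _oracles import oracle_disk_cdf, oracle_disk_quantile

from dbmap import (
    CaseSet,
    DistanceCDF,
    StepCDF,
    band_limits,
    build_scheme,
    calibrate_palette,
    compute_map,
    discretize_reference,
    empirical_distance_cdf,
    gamma_projection,
    make_circle_points,
    prepare_projection_contexts,
    uniform_disk_distance_cdf,
)


class Uniform01CDF(DistanceCDF):
    """Uniform distance distribution on [0, 1] — a transparent toy reference."""

    support = (0.0, 1.0)

    def evaluate(self, d):
        return np.clip(np.asarray(d, dtype=float), 0.0, 1.0)

    def inverse(self, q):
        return np.clip(np.asarray(q, dtype=float), 0.0, 1.0)


class TestEmpiricalCDF:
    def test_single_case(self):
        cases = CaseSet.from_points([(0.3, 0.0)])
        F = empirical_distance_cdf(cases, (0.0, 0.0))
        assert F.evaluate(0.29) == 0.0
        assert F.evaluate(0.3) == 1.0

    def test_discrete_counts_give_weighted_steps(self):
        centroids = [(0.1, 0.0), (0.25, 0.0), (0.5, 0.0), (0.8, 0.0)]
        cases = CaseSet.from_counts(centroids, [4.0, 2.0, 2.0, 4.0])
        F = empirical_distance_cdf(cases, (0.0, 0.0))
        np.testing.assert_allclose(F.weights, [1 / 3, 1 / 6, 1 / 6, 1 / 3])

    def test_ecdf_converges_to_reference(self, uniform_reference):
        """Dvoretzky-Kiefer-Wolfowitz: sup|Fhat - F0| < 1.36/sqrt(n) holds in
        ~95% of trials at n = 1000."""
        c = np.array([1.0, 0.0])
        F0 = uniform_reference.distance_cdf(c)
        n, trials, ok = 1000, 200, 0
        rng = np.random.default_rng(99)
        for _ in range(trials):
            pts = uniform_reference.sample(n, rng)
            d = np.sort(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]))
            f0 = F0.evaluate(d)
            steps = np.arange(1, n + 1) / n
            ks = max(np.abs(f0 - steps).max(), np.abs(f0 - steps + 1 / n).max())
            ok += ks < 1.36 / np.sqrt(n)
        assert ok >= 0.90 * trials

    def test_zero_total_count_rejected(self):
        with pytest.raises(ValueError):
            CaseSet.from_counts([(0, 0)], [0.0])


class TestBandLimits:
    def test_uniform_reference_band(self):
        lo, hi = band_limits(Uniform01CDF(), 0.5, 0.1)
        assert (lo, hi) == pytest.approx((0.45, 0.55))

    def test_clipped_at_lower_edge(self):
        lo, hi = band_limits(Uniform01CDF(), 0.02, 0.1)
        assert (lo, hi) == pytest.approx((0.0, 0.07))

    def test_band_content_equals_p0_when_unclipped(self):
        F0 = uniform_disk_distance_cdf((1.5, 0.0))
        for q in (0.2, 0.5, 0.8):
            t = F0.inverse(q)
            lo, hi = band_limits(F0, t, 0.2)
            assert F0.evaluate(hi) - F0.evaluate(lo) == pytest.approx(0.2, abs=1e-6)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            band_limits(Uniform01CDF(), 0.5, 0.0)


class TestGammaProjection:
    def test_zero_when_observed_equals_expected(self):
        F0 = StepCDF([0.2, 0.5, 0.9], [0.3, 0.4, 0.3])
        g = gamma_projection((0.0, 0.0), (1.0, 0.0), F0, F0, 0.1)
        assert g == 0.0

    def test_positive_when_all_cases_at_y(self, projections20):
        """All case mass at y: the band around t always contains the single
        observed distance, so gamma = 1 - (expected mass) > 0."""
        y = np.array([0.0, 0.0])
        cases = CaseSet.from_points([y, y, y])
        for c in projections20.points[:5]:
            F0 = uniform_disk_distance_cdf(c)
            Fhat = empirical_distance_cdf(cases, c)
            assert gamma_projection(y, c, Fhat, F0, 0.1) > 0

    def test_matches_independent_dense_oracle(self, uniform_reference):
        rng = np.random.default_rng(4)
        pts = uniform_reference.sample(3, rng)
        cases = CaseSet.from_points(pts)
        c = np.array([2.0, 0.0])
        F0 = uniform_disk_distance_cdf(c)
        Fhat = empirical_distance_cdf(cases, c)
        y = np.array([0.0, 0.0])
        got = gamma_projection(y, c, Fhat, F0, 0.2)
        t = float(np.hypot(*(y - c)))
        q = oracle_disk_cdf(t, 2.0)[0]
        lo = oracle_disk_quantile([max(q - 0.1, 0.0)], 2.0)[0]
        hi = oracle_disk_quantile([min(q + 0.1, 1.0)], 2.0)[0]
        d, w = cases.distance_weights(c)
        obs = w[(d > lo) & (d <= hi)].sum()
        exp = oracle_disk_cdf(hi, 2.0)[0] - oracle_disk_cdf(lo, 2.0)[0]
        assert got == pytest.approx(obs - exp, abs=1e-6)


class TestComputeMap:
    def test_rotation_equivariance(self, unit_disk, uniform_reference, coarse_grid):
        """Rotating cases and projections by a quarter turn permutes the
        scores exactly with the grid rotation."""
        proj = make_circle_points(unit_disk, 8)
        rng = np.random.default_rng(11)
        pts = uniform_reference.sample(40, rng)
        m1 = compute_map(CaseSet.from_points(pts), uniform_reference, proj, coarse_grid, 0.1)
        rot = np.column_stack([-pts[:, 1], pts[:, 0]])
        m2 = compute_map(CaseSet.from_points(rot), uniform_reference, proj, coarse_grid, 0.1)
        # match each rotated grid point to its index in the original grid
        grid_rot = np.column_stack([-coarse_grid.points[:, 1], coarse_grid.points[:, 0]])
        order = {tuple(np.round(p, 12)): i for i, p in enumerate(coarse_grid.points)}
        perm = np.array([order[tuple(np.round(p, 12))] for p in grid_rot])
        np.testing.assert_allclose(m2.scores[perm], m1.scores, atol=1e-9)

    def test_discrete_continuous_coherence(self, unit_disk, projections20, coarse_grid):
        """Continuous cases sitting exactly on centroids give the same map as
        the aggregated counts."""
        scheme = build_scheme(unit_disk, 4, jitter_seed=5)
        from dbmap import UniformDiskReference

        reference = discretize_reference(UniformDiskReference(unit_disk), scheme, seed=1)
        counts = np.zeros(scheme.m)
        counts[[2, 5, 9, 12]] = [4, 2, 2, 4]
        discrete = CaseSet.from_counts(scheme.centroids, counts)
        pts = np.repeat(scheme.centroids, counts.astype(int), axis=0)
        continuous = CaseSet.from_points(pts)
        m_d = compute_map(discrete, reference, projections20, coarse_grid, 0.1)
        m_c = compute_map(continuous, reference, projections20, coarse_grid, 0.1)
        assert np.abs(m_d.scores - m_c.scores).max() <= 1e-12

    def test_null_score_magnitude_decreases_with_n(
        self, uniform_reference, projections20, coarse_grid
    ):
        """Consistency: under the null the score surface flattens as the
        sample grows."""
        rng = np.random.default_rng(3)
        ctx = prepare_projection_contexts(uniform_reference, projections20, coarse_grid, 0.1)
        maxima = {}
        for n in (100, 1000):
            vals = []
            for _ in range(20):
                cases = CaseSet.from_points(uniform_reference.sample(n, rng))
                m = compute_map(
                    cases, uniform_reference, projections20, coarse_grid, 0.1, contexts=ctx
                )
                vals.append(np.abs(m.scores).max())
            maxima[n] = np.median(vals)
        assert maxima[1000] < maxima[100]

    def test_context_reuse_matches_fresh_computation(
        self, uniform_reference, projections20, coarse_grid
    ):
        rng = np.random.default_rng(21)
        cases = CaseSet.from_points(uniform_reference.sample(30, rng))
        ctx = prepare_projection_contexts(uniform_reference, projections20, coarse_grid, 0.1)
        a = compute_map(cases, uniform_reference, projections20, coarse_grid, 0.1)
        b = compute_map(
            cases, uniform_reference, projections20, coarse_grid, 0.1, contexts=ctx
        )
        np.testing.assert_array_equal(a.scores, b.scores)


class TestPalette:
    @pytest.fixture(scope="module")
    @staticmethod
    def palette(uniform_reference, projections20, coarse_grid):
        return calibrate_palette(
            uniform_reference, 100, projections20, coarse_grid, 0.1, B=25, seed=8
        )

    def test_quantiles_monotone(self, palette):
        assert (np.diff(palette.thresholds) >= 0).all()
        assert palette.null_min <= palette.thresholds[0]
        assert palette.thresholds[-1] <= palette.null_max

    def test_same_seed_reproduces(self, uniform_reference, projections20, coarse_grid):
        a = calibrate_palette(uniform_reference, 50, projections20, coarse_grid, 0.1, B=19, seed=5)
        b = calibrate_palette(uniform_reference, 50, projections20, coarse_grid, 0.1, B=19, seed=5)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)
        assert (a.null_min, a.null_max) == (b.null_min, b.null_max)

    def test_small_B_rejected(self, uniform_reference, projections20, coarse_grid):
        with pytest.raises(ValueError):
            calibrate_palette(uniform_reference, 50, projections20, coarse_grid, 0.1, B=5)

    def test_unknown_level_rejected(self, palette):
        with pytest.raises(KeyError):
            palette.threshold(0.123)
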