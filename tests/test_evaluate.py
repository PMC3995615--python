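import numpy as np
import pytest

from _oracles import oracle_auc
from dbmap import (
    PaletteCalibration,
    RiskMap,
    average_centroid,
    build_scheme,
    did_metric,
    extract_high_region,
    label_grid,
    make_eval_grid,
    reasonable_extent,
    roc_auc,
)


class TestLabelGrid:
    def test_closed_square_membership(self, unit_disk):
        grid = make_eval_grid(unit_disk, 40)
        labels = label_grid(grid, (0.0, 0.0), 0.2)
        pts = grid.points
        inside = (np.abs(pts[:, 0]) <= 0.1) & (np.abs(pts[:, 1]) <= 0.1)
        assert np.array_equal(labels, inside)

    def test_positive_fraction_tracks_square_area(self, unit_disk):
        grid = make_eval_grid(unit_disk, 100)
        labels = label_grid(grid, (0.1, -0.2), 0.5)
        assert labels.mean() == pytest.approx(0.25 / np.pi, rel=0.05)

    def test_zero_diameter_labels_almost_nothing(self, coarse_grid):
        labels = label_grid(coarse_grid, (0.123456, 0.654321), 0.0)
        assert not labels.any()


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.9, 0.8], [False, False, True, True]) == 1.0

    def test_constant_scores(self):
        assert roc_auc([0.5] * 6, [True, False, True, False, False, True]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=50), 1)  # rounding forces ties
        labels = rng.random(50) < 0.3
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        assert roc_auc(scores, labels) == pytest.approx(oracle_auc(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        assert roc_auc(np.exp(scores), labels) == pytest.approx(roc_auc(scores, labels))


def _palette(thr95_range, levels=(0.95,)):
    """Minimal palette whose value scale tops out at thr95_range / 0.95."""
    return PaletteCalibration(
        levels=np.array([0.95]),
        thresholds=np.array([thr95_range]),
        B=99,
        n_resample=100,
        null_min=0.0,
        null_max=thr95_range / 0.95,
    )


class TestExtractHighRegion:
    def test_all_scores_below_threshold(self, coarse_grid):
        m = RiskMap(coarse_grid, np.zeros(coarse_grid.r))
        assert len(extract_high_region(m, _palette(0.5))) == 0

    def test_threshold_below_all_scores_selects_all(self, coarse_grid):
        m = RiskMap(coarse_grid, np.zeros(coarse_grid.r))
        palette = PaletteCalibration(
            levels=np.array([0.95]), thresholds=np.array([-1e9]), B=99,
            n_resample=100, null_min=-1e9, null_max=-1e9,
        )
        assert len(extract_high_region(m, palette)) == coarse_grid.r

    def test_selects_scores_at_or_above_break(self, coarse_grid):
        scores = np.zeros(coarse_grid.r)
        scores[[3, 7]] = 1.0
        m = RiskMap(coarse_grid, scores)
        got = extract_high_region(m, _palette(0.95))
        assert set(got) == {3, 7}


class TestReasonableExtent:
    def test_compact_blob_passes(self, unit_disk):
        grid = make_eval_grid(unit_disk, 100)
        center = np.array([0.1, 0.1])
        d = np.hypot(*(grid.points - center).T)
        subset = np.nonzero(d < 0.15)[0]  # hull diameter ~0.3
        assert reasonable_extent(subset, grid, 1 / 3)

    def test_two_distant_blobs_fail(self, unit_disk):
        grid = make_eval_grid(unit_disk, 100)
        d1 = np.hypot(*(grid.points - [-0.7, 0.0]).T)
        d2 = np.hypot(*(grid.points - [0.8, 0.0]).T)
        subset = np.nonzero((d1 < 0.1) | (d2 < 0.1))[0]
        assert not reasonable_extent(subset, grid, 1 / 3)

    def test_single_point_passes_any_side(self, coarse_grid):
        assert reasonable_extent([5], coarse_grid, 0.01)

    def test_collinear_subset_degenerates_gracefully(self, unit_disk):
        grid = make_eval_grid(unit_disk, 50)
        row = np.nonzero(np.isclose(grid.points[:, 1], grid.points[0, 1]))[0][:5]
        spread = float(np.ptp(grid.points[row][:, 0]))
        assert reasonable_extent(row, grid, spread) is True
        assert reasonable_extent(row, grid, spread / 10) is False

    def test_empty_subset_rejected(self, coarse_grid):
        with pytest.raises(ValueError):
            reasonable_extent([], coarse_grid, 0.5)


class TestAverageCentroid:
    def test_single_cell(self, unit_disk):
        scheme = build_scheme(unit_disk, 4, jitter_seed=0)
        pts = np.tile(scheme.centroids[3], (4, 1))
        np.testing.assert_allclose(average_centroid(pts, scheme), scheme.centroids[3])

    def test_weighted_mean_of_four_cells(self, unit_disk):
        """Counts 4/2/2/4 over four centroids weight them 0.4/0.2/0.2/0.4."""
        scheme = build_scheme(unit_disk, 4, jitter_seed=0)
        cells = [5, 6, 9, 10]
        counts = [4, 2, 2, 4]
        pts = np.repeat(scheme.centroids[cells], counts, axis=0)
        got = average_centroid(pts, scheme)
        want = np.average(scheme.centroids[cells], axis=0, weights=[0.4, 0.2, 0.2, 0.4])
        np.testing.assert_allclose(got, want)

    def test_empty_rejected(self, unit_disk):
        scheme = build_scheme(unit_disk, 4, jitter_seed=0)
        with pytest.raises(ValueError):
            average_centroid(np.empty((0, 2)), scheme)


class TestDidMetric:
    def test_zero_when_everything_coincides(self, coarse_grid):
        p = coarse_grid.points[10]
        assert did_metric([10], coarse_grid, p, p) == 0.0

    def test_positive_when_center_at_avg_centroid(self, coarse_grid):
        center = coarse_grid.points[10]
        focus = center + np.array([0.3, 0.0])
        assert did_metric([10], coarse_grid, focus, center) == pytest.approx(0.3)

    def test_negative_when_center_at_focus(self, coarse_grid):
        center = coarse_grid.points[10]
        avg = center + np.array([0.0, 0.4])
        assert did_metric([10], coarse_grid, center, avg) == pytest.approx(-0.4)
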