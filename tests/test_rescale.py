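import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipscale import (
    EstimationError,
    GenomeLayout,
    GridMismatchError,
    apply_scaling,
    estimate_scaling_factor,
    foldchange_distribution,
    input_consistency_check,
    make_bin_grid,
    select_outlier_bins,
    sensitivity_sweep,
)


@pytest.fixture
def grid6():
    return make_bin_grid(GenomeLayout((("chrA", 3000),)), 500)


class TestSelectOutlierBins:
    def test_top_k_by_value(self, grid6, make_track):
        t = make_track(grid6, [5, 1, 9, 0, 2, 3])
        bins = select_outlier_bins(t, k=2)
        assert bins.bin_indices.tolist() == [2, 0]
        assert bins.source_values.tolist() == [9, 5]

    def test_ties_broken_by_genomic_index(self, grid6, make_track):
        bins = select_outlier_bins(make_track(grid6, [4, 4, 4, 4, 4, 4]), k=3)
        assert bins.bin_indices.tolist() == [0, 1, 2]

    def test_k_out_of_range(self, grid6, make_track):
        t = make_track(grid6, [1, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError):
            select_outlier_bins(t, k=7)
        with pytest.raises(ValueError):
            select_outlier_bins(t, k=0)

    def test_requires_k_nonzero_bins(self, grid6, make_track):
        with pytest.raises(ValueError, match="nonzero"):
            select_outlier_bins(make_track(grid6, [5, 0, 0, 0, 0, 0]), k=2)


class TestFoldchangeDistribution:
    def test_identity_gives_median_one(self, grid6, make_track):
        t = make_track(grid6, [10, 20, 30, 40, 50, 60])
        bins = select_outlier_bins(t, 3)
        dist = foldchange_distribution(t, t, bins)
        assert dist.median_fc == 1.0 and dist.n_dropped == 0

    def test_hand_computed_ratios(self, grid6, make_track):
        u = make_track(grid6, [100, 90, 80, 1, 1, 1])
        t = make_track(grid6, [200, 171, 168, 1, 1, 1])
        dist = foldchange_distribution(t, u, select_outlier_bins(u, 3))
        assert sorted(dist.per_bin_fc.tolist()) == pytest.approx([1.9, 2.0, 2.1])
        assert dist.median_fc == pytest.approx(2.0)

    def test_zero_bins_dropped_and_counted(self, grid6, make_track):
        u = make_track(grid6, [100, 90, 80, 1, 1, 1])
        t = make_track(grid6, [200, 0, 160, 1, 1, 1])
        dist = foldchange_distribution(t, u, select_outlier_bins(u, 3))
        assert dist.n_used == 2 and dist.n_dropped == 1

    def test_all_dropped_raises(self, grid6, make_track):
        u = make_track(grid6, [100, 90, 80, 1, 1, 1])
        t = make_track(grid6, [0, 0, 0, 1, 1, 1])
        with pytest.raises(EstimationError):
            foldchange_distribution(t, u, select_outlier_bins(u, 3))

    def test_grid_mismatch(self, grid6, make_track):
        other = make_bin_grid(GenomeLayout((("chrA", 3000),)), 250)
        u = make_track(grid6, [1, 2, 3, 4, 5, 6])
        t = make_track(other, np.ones(12))
        with pytest.raises(GridMismatchError):
            foldchange_distribution(t, u, select_outlier_bins(u, 2))


class TestEstimateScalingFactor:
    def test_identical_tracks(self, grid6, make_track):
        t = make_track(grid6, [10, 20, 30, 40, 50, 60])
        assert estimate_scaling_factor(t, t, k=3).factor == 1.0

    def test_doubled_track(self, grid6, make_track):
        u = make_track(grid6, [10, 20, 30, 40, 50, 60])
        t = make_track(grid6, 2 * u.values)
        assert estimate_scaling_factor(t, u, k=3).factor == pytest.approx(0.5)

    def test_scale_equivariance(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        t = make_track(grid6, [13, 20, 39, 40, 60, 62])
        base = estimate_scaling_factor(t, u, k=4).factor
        for c in (0.3, 2.0, 7.5):
            scaled = estimate_scaling_factor(make_track(grid6, c * t.values), u, k=4).factor
            assert scaled == pytest.approx(base / c, rel=1e-12)

    def test_self_normalization(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        t = make_track(grid6, [17, 22, 39, 41, 66, 61])
        res = estimate_scaling_factor(t, u, k=4)
        bins = select_outlier_bins(u, 4)
        dist = foldchange_distribution(apply_scaling(t, res.factor), u, bins)
        assert dist.median_fc == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_treated_signal(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        t = make_track(grid6, [17, 22, 39, 41, 66, 61])
        f1 = estimate_scaling_factor(t, u, k=4).factor
        f2 = estimate_scaling_factor(make_track(grid6, t.values * 1.2), u, k=4).factor
        assert f2 < f1


class TestInputConsistency:
    def test_exact_proportionality(self, grid6, make_track):
        iu = make_track(grid6, [50, 40, 30, 20, 10, 5])
        it = make_track(grid6, 1.3 * iu.values)
        bins = select_outlier_bins(iu, 3)
        rep = input_consistency_check(it, iu, bins)
        assert rep.total_fc == pytest.approx(1.3)
        assert rep.outlier_median_fc == pytest.approx(1.3)
        assert rep.abs_log2_gap == pytest.approx(0.0, abs=1e-12)
        assert rep.consistent

    def test_zero_total_raises(self, grid6, make_track):
        iu = make_track(grid6, [50, 40, 30, 20, 10, 5])
        bins = select_outlier_bins(iu, 3)
        with pytest.raises(EstimationError):
            input_consistency_check(make_track(grid6, np.zeros(6)), iu, bins)


class TestSensitivitySweep:
    def test_proportional_tracks_have_zero_spread(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        t = make_track(grid6, 1.6 * u.values)
        rep = sensitivity_sweep(t, u, [1, 2, 3, 4])
        assert rep.factors == pytest.approx([1 / 1.6] * 4)
        assert rep.relative_spread == 0.0

    def test_single_k_degenerate(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        rep = sensitivity_sweep(u, u, [3])
        assert rep.factors == [1.0] and rep.relative_spread == 0.0

    def test_invalid_k_named(self, grid6, make_track):
        u = make_track(grid6, [10, 25, 30, 45, 50, 65])
        with pytest.raises(ValueError, match="99"):
            sensitivity_sweep(u, u, [3, 99])


class TestApplyScaling:
    def test_identity_and_inverse(self, grid6, make_track):
        t = make_track(grid6, [1.0, 2.0, 0.0, 4.0, 5.0, 6.0])
        assert apply_scaling(t, 1.0).values.tolist() == t.values.tolist()
        back = apply_scaling(apply_scaling(t, 0.5), 2.0)
        np.testing.assert_allclose(back.values, t.values)
        assert back.total_bases == pytest.approx(t.total_bases)

    def test_constant_track(self, grid6, make_track):
        scaled = apply_scaling(make_track(grid6, np.ones(6)), 0.57)
        assert scaled.values.tolist() == pytest.approx([0.57] * 6)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_nonpositive_factor_rejected(self, grid6, make_track, factor):
        with pytest.raises(ValueError):
            apply_scaling(make_track(grid6, np.ones(6)), factor)


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10))
def test_property_scale_equivariance_random_tracks(seed, c):
    """estimate(c * treated, untreated) == estimate(treated, untreated) / c."""
    rng = np.random.default_rng(seed)
    grid = make_bin_grid(GenomeLayout((("s", 10_000),)), 500)
    u = rng.gamma(2.0, 2.0, grid.n_bins) + 0.1
    t = rng.gamma(2.0, 2.0, grid.n_bins) + 0.1
    from conftest import track

    base = estimate_scaling_factor(track(grid, t), track(grid, u), k=10).factor
    scaled = estimate_scaling_factor(track(grid, c * t), track(grid, u), k=10).factor
    assert scaled == pytest.approx(base / c, rel=1e-9)
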