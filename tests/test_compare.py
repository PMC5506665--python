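import numpy as np
import pandas as pd
import pytest

from chipscale import (
    EstimationError,
    FormatError,
    GenomeLayout,
    genomewide_correlation,
    make_bin_grid,
    per_bin_foldchange,
    promoter_windows,
    sorted_promoter_foldchange,
    window_signal,
)


@pytest.fixture
def grid8():
    return make_bin_grid(GenomeLayout((("chrA", 4000),)), 500)


class TestGenomewideCorrelation:
    def test_self_correlation_is_one(self, grid8, make_track):
        t = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        assert genomewide_correlation(t, t).r == pytest.approx(1.0)

    def test_rescaling_invariance(self, grid8, make_track):
        x = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        y = make_track(grid8, [2, 1, 4, 3, 6, 5, 8, 7])
        base = genomewide_correlation(x, y).r
        for c in (0.57, 3.0):
            scaled = genomewide_correlation(x, make_track(grid8, c * y.values)).r
            assert abs(scaled - base) < 1e-12

    def test_known_value(self, grid8, make_track):
        # r computed directly from the Pearson formula for these points
        x = make_track(grid8, [1, 2, 3, 4, 0, 0, 0, 0])
        y = make_track(grid8, [1.1, 1.9, 3.2, 3.8, 0, 0, 0, 0])
        res = genomewide_correlation(x, y)
        assert res.r == pytest.approx(0.990847, abs=1e-6)
        assert res.n_bins_used == 4  # all-zero bins excluded

    def test_zero_variance_raises(self, grid8, make_track):
        flat = make_track(grid8, np.ones(8))
        other = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        with pytest.raises(EstimationError):
            genomewide_correlation(flat, other)

    def test_log_transform_reported(self, grid8, make_track):
        x = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        y = make_track(grid8, [8, 7, 6, 5, 4, 3, 2, 1])
        assert genomewide_correlation(x, y, transform="log2p1").transform == "log2p1"


class TestPerBinFoldchange:
    def test_identity(self, grid8, make_track):
        t = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        fc = per_bin_foldchange(t, t)
        assert np.all(fc.values[fc.defined] == 1.0)

    def test_uniform_reduction(self, grid8, make_track):
        u = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        t = make_track(grid8, 0.57 * u.values)
        fc = per_bin_foldchange(t, u)
        assert fc.values[fc.defined] == pytest.approx(0.57)

    def test_undefined_flagged_not_dropped(self, grid8, make_track):
        u = make_track(grid8, [1, 0, 3, 0, 5, 6, 7, 8])
        t = make_track(grid8, np.ones(8))
        fc = per_bin_foldchange(t, u)
        assert fc.defined.tolist() == [True, False, True, False, True, True, True, True]
        assert np.isnan(fc.values[1])


def genes(*rows):
    return pd.DataFrame(rows, columns=["sequence", "start", "end", "gene_id", "strand"])


class TestPromoterWindows:
    def test_plus_strand_tss_at_start(self):
        layout = GenomeLayout((("chrA", 100_000),))
        w = promoter_windows(genes(("chrA", 10_000, 15_000, "g1", "+")), layout)
        rec = w.features.iloc[0]
        assert (rec.tss, rec.start, rec.end) == (10_000, 8_000, 12_000)

    def test_minus_strand_tss_at_end(self):
        layout = GenomeLayout((("chrA", 100_000),))
        w = promoter_windows(genes(("chrA", 10_000, 15_000, "g1", "-")), layout)
        rec = w.features.iloc[0]
        assert (rec.tss, rec.start, rec.end) == (15_000, 13_000, 17_000)

    def test_clipped_at_sequence_start(self):
        layout = GenomeLayout((("chrA", 100_000),))
        w = promoter_windows(genes(("chrA", 500, 5_000, "g1", "+")), layout)
        rec = w.features.iloc[0]
        assert (rec.start, rec.end) == (0, 2_500)

    def test_invalid_strand_rejected(self):
        layout = GenomeLayout((("chrA", 100_000),))
        with pytest.raises(FormatError, match="strand"):
            promoter_windows(genes(("chrA", 500, 5_000, "g1", ".")), layout)

    def test_unknown_sequence_rejected(self):
        layout = GenomeLayout((("chrA", 100_000),))
        with pytest.raises(FormatError, match="chrZ"):
            promoter_windows(genes(("chrZ", 500, 5_000, "g1", "+")), layout)

    def test_one_window_per_gene_full_width(self):
        layout = GenomeLayout((("chrA", 100_000),))
        ann = genes(("chrA", 10_000, 15_000, "g1", "+"), ("chrA", 50_000, 51_000, "g2", "-"))
        w = promoter_windows(ann, layout)
        assert len(w.features) == 2
        assert ((w.features.end - w.features.start) == 4000).all()


class TestWindowSignal:
    def test_constant_track(self, grid8, make_track):
        layout = grid8.layout
        w = promoter_windows(genes(("chrA", 2000, 3000, "g1", "+")), layout, flank=500)
        sig = window_signal(make_track(grid8, 2.5 * np.ones(8)), w)
        assert sig[0] == pytest.approx(2.5)

    def test_window_on_single_bin(self, grid8, make_track):
        t = make_track(grid8, [1, 7, 1, 1, 1, 1, 1, 1])
        w = promoter_windows(genes(("chrA", 750, 3000, "g1", "+")), layout=grid8.layout, flank=250)
        # window [500, 1000) is exactly bin 1
        assert window_signal(t, w)[0] == pytest.approx(7.0)

    def test_overlap_weighted_average(self, grid8, make_track):
        t = make_track(grid8, [1, 3, 1, 1, 1, 1, 1, 1])
        w = promoter_windows(genes(("chrA", 500, 3000, "g1", "+")), layout=grid8.layout, flank=250)
        # window [250, 750): half in bin 0 (value 1), half in bin 1 (value 3)
        assert window_signal(t, w)[0] == pytest.approx(2.0)


class TestSortedPromoterFoldchange:
    def test_identical_tracks(self, grid8, make_track):
        t = make_track(grid8, [1, 2, 3, 4, 5, 6, 7, 8])
        ann = genes(("chrA", 1000, 2000, "g1", "+"), ("chrA", 3000, 3500, "g2", "+"))
        w = promoter_windows(ann, grid8.layout, flank=500)
        table, summary = sorted_promoter_foldchange(t, t, w)
        assert table.fold_change.tolist() == pytest.approx([1.0, 1.0])
        assert summary["fraction_below_1"] == 0.0

    def test_two_gene_exact_ratios_sorted(self, grid8, make_track):
        u = make_track(grid8, [2, 2, 2, 2, 4, 4, 4, 4])
        t = make_track(grid8, [1, 1, 1, 1, 6, 6, 6, 6])
        ann = genes(("chrA", 500, 1500, "gA", "+"), ("chrA", 2500, 3500, "gB", "+"))
        w = promoter_windows(ann, grid8.layout, flank=500)
        table, summary = sorted_promoter_foldchange(t, u, w)
        # gB: 6/4 = 1.5 ranks above gA: 1/2 = 0.5
        assert table.gene_id.tolist() == ["gB", "gA"]
        assert table.fold_change.tolist() == pytest.approx([1.5, 0.5])
        assert summary["fraction_below_1"] == 0.5

    def test_sorting_preserves_multiset(self, make_track):
        rng = np.random.default_rng(7)
        layout = GenomeLayout((("chrA", 100_000),))
        grid = make_bin_grid(layout, 500)
        u = make_track(grid, rng.gamma(3, 1, grid.n_bins) + 0.5)
        t = make_track(grid, rng.gamma(3, 1, grid.n_bins) + 0.5)
        ann = genes(*[("chrA", int(p), int(p) + 1000, f"g{i}", "+")
                      for i, p in enumerate(rng.integers(3000, 95_000, 30))])
        w = promoter_windows(ann, layout)
        table, _ = sorted_promoter_foldchange(t, u, w)
        assert sorted(table.fold_change) == pytest.approx(
            sorted(table.sort_values("gene_id").fold_change)
        )
        assert (table.fold_change.values[:-1] >= table.fold_change.values[1:]).all()

    def test_zero_untreated_flagged(self, grid8, make_track):
        u = make_track(grid8, [0, 0, 0, 0, 4, 4, 4, 4])
        t = make_track(grid8, np.ones(8))
        ann = genes(("chrA", 500, 1500, "gA", "+"), ("chrA", 2500, 3500, "gB", "+"))
        w = promoter_windows(ann, grid8.layout, flank=500)
        table, summary = sorted_promoter_foldchange(t, u, w)
        assert summary["n_defined"] == 1
        gA = table[table.gene_id == "gA"].iloc[0]
        assert not gA.defined and np.isnan(gA.fold_change)
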