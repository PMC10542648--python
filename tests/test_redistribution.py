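"""Quantile clusters, M-value rescaling, bin-change and promoter-change calls."""

import numpy as np
import pandas as pd
import pytest

from ubredist.genome_io import Genome
from ubredist.redistribution import (
    bin_change_classify,
    cluster_signal_test,
    frequency_vs_level_report,
    ma_normalize,
    promoter_change_classes,
    quantile_clusters,
)
from ubredist.signals import BinSignal, make_bins
from .conftest import make_peak


class TestQuantileClusters:
    def test_rank_quartiles_of_one_to_eight(self):
        assignment = quantile_clusters(np.array([1, 2, 3, 4, 5, 6, 7, 8.0]))
        assert assignment.labels == ["C1", "C1", "C2", "C2", "C3", "C3", "C4", "C4"]

    def test_all_equal_uses_coordinate_tie_break(self):
        peaks = [make_peak("chr1", s, s + 100) for s in (400, 300, 200, 100)]
        assignment = quantile_clusters(np.ones(4), peaks)
        # lowest coordinate → lowest cluster
        assert assignment.labels == ["C4", "C3", "C2", "C1"]

    def test_cluster_means_non_decreasing(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.gamma(2, 5, size=int(rng.integers(8, 200)))
            assignment = quantile_clusters(x)
            means = [x[assignment.members(c)].mean() for c in assignment.clusters]
            assert np.all(np.diff(means) >= 0)

    def test_sizes_differ_by_at_most_one(self):
        assignment = quantile_clusters(np.arange(11, dtype=float))
        sizes = [len(assignment.members(c)) for c in assignment.clusters]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 11

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            quantile_clusters(np.array([1.0, 2.0]), k=4)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestQuantileClusterProperties:
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_sizes_and_ordered_means(self, values):
        x = np.array(values)
        assignment = quantile_clusters(x)
        sizes = [len(assignment.members(c)) for c in assignment.clusters]
        assert sum(sizes) == len(x)
        assert max(sizes) - min(sizes) <= 1
        means = [x[assignment.members(c)].mean() for c in assignment.clusters]
        assert np.all(np.diff(means) >= 0)


class TestClusterSignalTest:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(23)
        hits = 0
        reps = 200
        for _ in range(reps):
            vals = {c: rng.normal(0, 1, 200) for c in ("C1", "C2", "C3", "C4")}
            out = cluster_signal_test(vals)
            hits += out["p_value"].iloc[0] < 0.05
        assert abs(hits / reps - 0.05) <= 0.03

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(24)
        vals = {c: rng.normal(0, 1, 200) for c in ("C1", "C2", "C3")}
        vals["C4"] = rng.normal(1, 1, 200)  # +1 SD shift
        out = cluster_signal_test(vals)
        c4_rows = out[(out["cluster_a"] == "C4") | (out["cluster_b"] == "C4")]
        assert (c4_rows["padj"] < 0.01).all()

    def test_identical_constant_samples_maximal_p(self):
        out = cluster_signal_test({"A": np.ones(5), "B": np.ones(5)})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_undersized_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_signal_test({"A": np.ones(2), "B": np.ones(5)})


class TestMANormalize:
    def test_equal_densities_zero_m_and_flat_fit(self):
        d = np.abs(np.random.default_rng(1).normal(10, 3, 100))
        res = ma_normalize(d, d.copy(), np.array(["common"] * 100))
        np.testing.assert_allclose(res.table["m_raw"], 0, atol=1e-12)
        assert res.slope == pytest.approx(0, abs=1e-9)

    def test_global_scaling_absorbed_by_fit(self):
        rng = np.random.default_rng(2)
        da = rng.gamma(4, 5, 300)
        res = ma_normalize(da, 2 * da, np.array(["common"] * 300))
        med = np.median(res.table["m_rescaled"])
        assert abs(med) < 0.05

    def test_planted_affine_trends_removed(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a0, b0 = rng.uniform(-2, 2), rng.uniform(-0.5, 0.5)
            a_lat = rng.normal(4, 1, 400)
            m_lat = a0 + b0 * a_lat + rng.normal(0, 0.05, 400)
            da = 2 ** (a_lat + m_lat / 2)
            db = 2 ** (a_lat - m_lat / 2)
            res = ma_normalize(da, db, np.array(["common"] * 400))
            assert abs(np.median(res.table["m_rescaled"])) < 0.05

    def test_planted_gain_subset_recovered(self):
        # density-level simulation: 20% of non-promoter peaks gain +2 log2
        rng = np.random.default_rng(1)
        n = 2000
        base = rng.gamma(4, 3, n)
        gain = np.zeros(n, dtype=bool)
        gain[rng.choice(n, 400, replace=False)] = True
        noise = rng.normal(0, 0.1, n)
        da = base * 2.0 ** (2.0 * gain + noise)
        db = base
        res = ma_normalize(da, db, np.array(["common"] * n))
        m = res.table["m_rescaled"].to_numpy()
        assert abs(m[gain].mean() - 2.0) < 0.3
        assert abs(m[~gain].mean()) < 0.2

    def test_unique_peaks_get_extrapolated_rescaling(self):
        rng = np.random.default_rng(3)
        da = rng.gamma(4, 5, 120)
        side = np.array(["common"] * 100 + ["unique_a"] * 20)
        db = da.copy()
        db[100:] = 0.0  # unique to A: no signal in B
        res = ma_normalize(da, db, side)
        uniq = res.table[res.table["side"] == "unique_a"]
        assert (uniq["m_rescaled"] > 3).all()  # strongly A-specific after rescaling

    def test_significant_peaks_have_small_p(self):
        rng = np.random.default_rng(4)
        da = rng.gamma(4, 5, 200)
        db = da.copy()
        db[:20] = da[:20] / 8  # strong gains in A
        res = ma_normalize(da, db, np.array(["common"] * 200),
                           peak_lengths=np.full(200, 2000.0))
        assert (res.table["padj"][:20] < 0.05).all()

    def test_too_few_common_peaks_rejected(self):
        with pytest.raises(ValueError, match="common"):
            ma_normalize(np.ones(5), np.ones(5), np.array(["common"] * 5))


class TestBinChangeClassify:
    def grid_signals(self, n_per_chrom=10):
        g = Genome(("chr1",), (n_per_chrom * 2000,))
        grid = make_bins(g, 2000)
        return grid

    def test_no_change_all_unchanged(self):
        grid = self.grid_signals()
        v = np.abs(np.random.default_rng(0).normal(5, 1, grid.n_bins))
        s = lambda x: BinSignal(grid, x)
        out = bin_change_classify(s(v), s(v.copy()), s(v), s(v.copy()))
        assert (out.table["change_class"] == "unchanged").all()

    def test_thresholded_classes(self):
        grid = self.grid_signals(4)
        up = np.array([8.0, 2.0, 2.0, 2.0])
        base = np.array([2.0, 2.0, 2.0, 2.0])
        down = np.array([0.4, 2.0, 2.0, 2.0])
        s = lambda x: BinSignal(grid, x)
        out = bin_change_classify(s(up), s(base), s(up), s(base))
        assert out.table["change_class"][0] == "both_up"
        out = bin_change_classify(s(down), s(base), s(down), s(base))
        assert out.table["change_class"][0] == "both_down"
        out = bin_change_classify(s(up), s(base), s(down), s(base))
        assert out.table["change_class"][0] == "discordant"

    def test_swapping_conditions_flips_classes(self):
        grid = self.grid_signals()
        rng = np.random.default_rng(5)
        a, b = rng.gamma(3, 2, grid.n_bins), rng.gamma(3, 2, grid.n_bins)
        c, d = rng.gamma(3, 2, grid.n_bins), rng.gamma(3, 2, grid.n_bins)
        s = lambda x: BinSignal(grid, x)
        fwd = bin_change_classify(s(a), s(b), s(c), s(d)).table["change_class"]
        rev = bin_change_classify(s(b), s(a), s(d), s(c)).table["change_class"]
        swap = {"both_up": "both_down", "both_down": "both_up",
                "discordant": "discordant", "unchanged": "unchanged"}
        assert list(rev) == [swap[c_] for c_ in fwd]

    def test_proportions_sum_to_one_per_stratum(self):
        grid = self.grid_signals(40)
        rng = np.random.default_rng(6)
        s = lambda: BinSignal(grid, rng.gamma(2, 2, grid.n_bins))
        region = np.array(["promoter", "non_promoter"] * (grid.n_bins // 2), dtype=object)
        out = bin_change_classify(s(), s(), s(), s(), region_class=region)
        props = out.proportions(by_region=True)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_grid_mismatch_rejected(self):
        g1 = make_bins(Genome(("chr1",), (20_000,)), 2000)
        g2 = make_bins(Genome(("chr1",), (20_000,)), 1000)
        s1 = BinSignal(g1, np.ones(g1.n_bins))
        s2 = BinSignal(g2, np.ones(g2.n_bins))
        with pytest.raises(ValueError, match="grid"):
            bin_change_classify(s1, s1, s2, s2)


class TestPromoterChangeClasses:
    @pytest.mark.parametrize(
        "m,expected",
        [(-2.0, "lost"), (0.3, "unchanged"), (-0.5, "unchanged"),
         (0.5, "unchanged"), (-1.0, "other"), (-1.5, "other"), (1.2, "other")],
    )
    def test_band_thresholds(self, m, expected):
        out = promoter_change_classes(np.array([m]))
        assert out["change_class"][0] == expected

    def test_classes_exhaustive_and_disjoint(self):
        m = np.random.default_rng(0).normal(0, 2, 500)
        out = promoter_change_classes(m)
        assert set(out["change_class"]) <= {"unchanged", "lost", "other"}
        assert len(out) == 500


class TestFrequencyVsLevelReport:
    def make_assignment(self, freqs):
        intens = np.arange(8, dtype=float)
        assignment = quantile_clusters(intens)
        frequencies = {c: {"frequency": f, "n": 2} for c, f in
                       zip(assignment.clusters, freqs)}
        return assignment, frequencies, intens

    def test_monotone_frequencies_give_rho_one(self):
        assignment, freqs, intens = self.make_assignment([0.1, 0.2, 0.4, 0.8])
        table, rho = frequency_vs_level_report(assignment, freqs, intens)
        assert rho == pytest.approx(1.0)
        assert len(table) == 4

    def test_flat_frequencies_reported_without_rho(self):
        assignment, freqs, intens = self.make_assignment([0.3, 0.3, 0.3, 0.3])
        table, rho = frequency_vs_level_report(assignment, freqs, intens)
        assert np.isnan(rho)  # degenerate: rank correlation undefined on ties-only

    def test_table_has_one_row_per_cluster(self):
        assignment, freqs, intens = self.make_assignment([0.0, 0.1, 0.5, 0.9])
        table, _ = frequency_vs_level_report(assignment, freqs, intens,
                                             ring1b_density=intens * 2)
        assert list(table["cluster"]) == ["C1", "C2", "C3", "C4"]
        assert table["mean_intensity"].is_monotonic_increasing
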