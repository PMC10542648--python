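"""Signal arithmetic: binning, normalization, intensity, anchor matrices."""

import numpy as np
import pytest

from ubredist.genome_io import CoverageTrack, Genome, Interval, Peak
from ubredist.signals import (
    BinSignal,
    anchor_matrix,
    bin_correlation,
    binned_average,
    call_simple_peaks,
    filter_blacklist,
    log2_signal,
    make_bins,
    metaprofile,
    peak_intensity,
    rpgc_normalize,
    step_averages,
)
from .conftest import make_peak, per_base, random_track


def constant_track(genome, value):
    return CoverageTrack(
        genome,
        {c: (np.array([0]), np.array([genome.length_of(c)]), np.array([value]))
         for c in genome.chrom_names},
    )


class TestMakeBins:
    def test_truncated_last_bin(self):
        g = Genome(("chr1",), (5000,))
        grid = make_bins(g, 2000)
        assert list(zip(grid.starts, grid.ends)) == [(0, 2000), (2000, 4000), (4000, 5000)]

    def test_bin_larger_than_chromosome(self):
        g = Genome(("chr1",), (1500,))
        grid = make_bins(g, 2000)
        assert grid.n_bins == 1 and grid.ends[0] == 1500

    def test_total_count_ceil_arithmetic(self):
        g = Genome(("chr1", "chr2"), (1_000_000, 500_000))
        assert make_bins(g, 2000).n_bins == 750  # 500 + 250

    def test_bins_tile_exhaustively(self, tiny_genome):
        grid = make_bins(tiny_genome, 777)
        assert int(grid.lengths().sum()) == tiny_genome.total_length


class TestBinnedAverage:
    def test_constant_track_identity(self, tiny_genome):
        grid = make_bins(tiny_genome, 2000)
        sig = binned_average(constant_track(tiny_genome, 3.5), grid)
        np.testing.assert_allclose(sig.values, 3.5)

    def test_hand_computed_partial_run(self, tiny_genome):
        track = CoverageTrack(
            tiny_genome, {"chr1": (np.array([0]), np.array([500]), np.array([4.0]))}
        )
        sig = binned_average(track, make_bins(tiny_genome, 2000))
        assert sig.values[0] == pytest.approx(1.0)  # 4·500/2000
        assert sig.values[1] == 0.0

    def test_matches_per_base_oracle_on_random_tracks(self, tiny_genome):
        rng = np.random.default_rng(11)
        grid = make_bins(tiny_genome, 512)
        for _ in range(50):
            track = random_track(tiny_genome, rng)
            sig = binned_average(track, grid)
            for ci, chrom in enumerate(tiny_genome.chrom_names):
                dense = per_base(track, chrom)
                mask = grid.chroms == ci
                expected = [dense[s:e].mean() for s, e in
                            zip(grid.starts[mask], grid.ends[mask])]
                np.testing.assert_allclose(sig.values[mask], expected, atol=1e-9)


class TestRPGC:
    def test_scaling_law(self, tiny_genome):
        egs = tiny_genome.total_length
        track = constant_track(tiny_genome, 2.0)  # total = 2 × EGS
        out = rpgc_normalize(track, egs, 1.0)
        assert out.total_signal() == pytest.approx(egs)
        np.testing.assert_allclose(out.runs["chr1"][2], 1.0)

    def test_mean_is_scale_factor(self, tiny_genome):
        rng = np.random.default_rng(5)
        track = random_track(tiny_genome, rng)
        egs = tiny_genome.total_length
        out = rpgc_normalize(track, egs, 1.0)
        assert out.total_signal() / egs == pytest.approx(1.0, abs=1e-9)
        out2 = rpgc_normalize(track, egs, 2.0)
        for c in out.runs:
            np.testing.assert_allclose(out2.runs[c][2], 2.0 * out.runs[c][2])

    def test_idempotent_at_scale_one(self, tiny_genome):
        rng = np.random.default_rng(6)
        track = random_track(tiny_genome, rng)
        once = rpgc_normalize(track, tiny_genome.total_length)
        twice = rpgc_normalize(once, tiny_genome.total_length)
        for c in once.runs:
            np.testing.assert_allclose(twice.runs[c][2], once.runs[c][2], atol=1e-9)

    def test_empty_track_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="empty signal"):
            rpgc_normalize(CoverageTrack(tiny_genome), 1000)


class TestPeakIntensity:
    def test_top_five_of_six_steps(self, tiny_genome):
        vals = [5, 4, 3, 2, 1, 0.5]
        starts = np.arange(6) * 100
        track = CoverageTrack(
            tiny_genome, {"chr1": (starts, starts + 100, np.array(vals, dtype=float))}
        )
        (out,) = peak_intensity(track, [make_peak("chr1", 0, 600)])
        assert out == pytest.approx(3.0)  # (5+4+3+2+1)/5

    def test_fewer_than_five_steps_uses_all(self, tiny_genome):
        starts = np.arange(3) * 100
        track = CoverageTrack(
            tiny_genome, {"chr1": (starts, starts + 100, np.array([2.0, 4.0, 6.0]))}
        )
        (out,) = peak_intensity(track, [make_peak("chr1", 0, 300)])
        assert out == pytest.approx(4.0)

    def test_constant_track_identity(self, tiny_genome):
        track = constant_track(tiny_genome, 7.0)
        peaks = [make_peak("chr1", 100, 1500), make_peak("chr2", 0, 250)]
        np.testing.assert_allclose(peak_intensity(track, peaks), 7.0)

    def test_invariant_to_run_splitting(self, tiny_genome):
        whole = CoverageTrack(
            tiny_genome, {"chr1": (np.array([0]), np.array([1000]), np.array([5.0]))}
        )
        split = CoverageTrack(
            tiny_genome,
            {"chr1": (np.array([0, 400]), np.array([400, 1000]), np.array([5.0, 5.0]))},
        )
        peaks = [make_peak("chr1", 50, 950)]
        assert peak_intensity(whole, peaks)[0] == peak_intensity(split, peaks)[0]


class TestLog2Signal:
    def test_zero_with_pseudocount(self):
        assert log2_signal([0.0], 0.01)[0] == pytest.approx(np.log2(0.01))

    def test_monotone_and_small_pseudocount_limit(self):
        out = log2_signal([1.0, 2.0, 3.0], 1e-12)
        assert out[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(out) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_signal([-1.0])


class TestAnchorMatrix:
    def test_constant_track_flat_profile(self, tiny_genome):
        track = constant_track(tiny_genome, 2.0)
        mat = anchor_matrix(track, [("chr1", 5000), ("chr2", 4000)], flank=1000, step=100)
        np.testing.assert_allclose(mat.matrix, 2.0)
        np.testing.assert_allclose(metaprofile(mat), 2.0)

    def test_spike_lands_in_center_column(self, tiny_genome):
        track = CoverageTrack(
            tiny_genome, {"chr1": (np.array([5000]), np.array([5100]), np.array([9.0]))}
        )
        mat = anchor_matrix(track, [("chr1", 5000)], flank=1000, step=100)
        center = len(mat.offsets) // 2  # first column at offset 0
        assert np.argmax(mat.matrix[0]) == center

    def test_edge_windows_zero_padded(self, tiny_genome):
        track = constant_track(tiny_genome, 1.0)
        mat = anchor_matrix(track, [("chr1", 0)], flank=1000, step=100)
        assert mat.n_clipped == 1
        assert np.all(mat.matrix[0, :10] == 0)  # upstream of position 0
        np.testing.assert_allclose(mat.matrix[0, 10:], 1.0)

    def test_matches_per_base_oracle(self, tiny_genome):
        rng = np.random.default_rng(21)
        for _ in range(50):
            track = random_track(tiny_genome, rng)
            anchors = [("chr1", int(rng.integers(1000, 9000))) for _ in range(5)]
            mat = anchor_matrix(track, anchors, flank=500, step=50)
            dense = per_base(track, "chr1")
            for i, (_, pos) in enumerate(anchors):
                expected = [dense[pos + o : pos + o + 50].mean() for o in mat.offsets]
                np.testing.assert_allclose(mat.matrix[i], expected, atol=1e-9)
            np.testing.assert_allclose(metaprofile(mat), mat.matrix.mean(axis=0), atol=1e-12)


class TestBinCorrelation:
    def test_scaled_signal_gives_r_one(self, tiny_genome):
        rng = np.random.default_rng(8)
        grid = make_bins(tiny_genome, 1000)
        a = np.abs(rng.normal(5, 2, grid.n_bins))
        r, n = bin_correlation(BinSignal(grid, a), BinSignal(grid, 2 * a), pseudocount=1e-9)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert n == grid.n_bins

    def test_shuffled_signal_near_zero(self):
        g = Genome(("chr1",), (10_000_000,))
        grid = make_bins(g, 1000)
        rng = np.random.default_rng(9)
        a = np.abs(rng.normal(5, 2, grid.n_bins))
        b = rng.permutation(a)
        r, _ = bin_correlation(BinSignal(grid, a), BinSignal(grid, b))
        assert abs(r) < 0.05

    def test_anti_ordered_pair(self, tiny_genome):
        grid = make_bins(tiny_genome, 1000)
        a = 2.0 ** np.arange(grid.n_bins)  # log2 scale is exactly linear
        r, _ = bin_correlation(BinSignal(grid, a), BinSignal(grid, a[::-1].copy()),
                               pseudocount=1e-9)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_rejected(self, tiny_genome):
        grid = make_bins(tiny_genome, 1000)
        with pytest.raises(ValueError, match="variance"):
            bin_correlation(BinSignal(grid, np.ones(grid.n_bins)),
                            BinSignal(grid, np.arange(grid.n_bins, dtype=float)))


class TestSimplePeakCaller:
    def test_subthreshold_track_empty(self, tiny_genome):
        assert call_simple_peaks(constant_track(tiny_genome, 0.5), threshold=1.0) == []

    def test_rectangular_region_exact_bounds(self, tiny_genome):
        track = CoverageTrack(
            tiny_genome, {"chr1": (np.array([2000]), np.array([3000]), np.array([5.0]))}
        )
        (peak,) = call_simple_peaks(track, threshold=1.0, min_len=200)
        assert (peak.start, peak.end) == (2000, 3000)

    def test_gap_merging(self, tiny_genome):
        track = CoverageTrack(
            tiny_genome,
            {"chr1": (np.array([1000, 2200]), np.array([2000, 3000]), np.array([5.0, 5.0]))},
        )
        merged = call_simple_peaks(track, 1.0, min_len=200, merge_gap=300)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (1000, 3000)
        split = call_simple_peaks(track, 1.0, min_len=200, merge_gap=100)
        assert len(split) == 2


def test_blacklist_filtering(tiny_genome):
    peaks = [make_peak("chr1", 0, 100), make_peak("chr1", 500, 700), make_peak("chr2", 0, 50)]
    black = [Interval("chr1", 600, 650)]
    kept = filter_blacklist(peaks, black)
    assert [(p.chrom, p.start) for p in kept] == [("chr1", 0), ("chr2", 0)]
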