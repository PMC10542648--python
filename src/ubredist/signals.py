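"""Coverage-signal arithmetic.

Implements the signal layer of the occupancy analysis: RPGC (1×) coverage
normalization, fixed-width genome binning with length-weighted averages,
top-five-step peak intensity, log2 transform, anchor matrices / metaprofiles,
bin-level Pearson correlation, and a minimal threshold peak caller used as
plumbing when only tracks are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import CoverageTrack, Genome, Interval, Peak

__all__ = [
    "BinGrid",
    "BinSignal",
    "AnchorMatrix",
    "make_bins",
    "binned_average",
    "rpgc_normalize",
    "peak_intensity",
    "step_averages",
    "log2_signal",
    "anchor_matrix",
    "metaprofile",
    "bin_correlation",
    "call_simple_peaks",
    "filter_blacklist",
]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling every chromosome; the last bin is truncated."""

    genome: Genome
    bin_size: int
    chroms: np.ndarray  # chrom index per bin
    starts: np.ndarray
    ends: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chroms == self.genome.chrom_names.index(chrom)

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass
class BinSignal:
    grid: BinGrid
    values: np.ndarray
    label: tuple[str, str] = ("", "")  # (condition, mark)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_bins:
            raise ValueError("value vector length != bin count")


@dataclass
class AnchorMatrix:
    """anchors × positions signal matrix around single-bp anchors."""

    offsets: np.ndarray  # left edge of each column window, bp from anchor
    step: int
    matrix: np.ndarray
    n_clipped: int = 0  # anchors whose window ran past a chromosome end


def make_bins(genome: Genome, bin_size: int = 2000) -> BinGrid:
    """Tile the genome with ``bin_size`` bins (default 2 kb)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends = [], [], []
    for ci, (name, length) in enumerate(zip(genome.chrom_names, genome.chrom_lengths)):
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        chroms.append(np.full(len(edges), ci, dtype=np.int64))
        starts.append(edges)
        ends.append(np.minimum(edges + bin_size, length))
    return BinGrid(
        genome,
        bin_size,
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(ends),
    )


def binned_average(track: CoverageTrack, grid: BinGrid,
                   label: tuple[str, str] = ("", "")) -> BinSignal:
    """Length-weighted mean coverage per bin (implicit zeros included)."""
    if track.genome != grid.genome:
        raise ValueError("track and grid use different genomes")
    values = np.empty(grid.n_bins)
    for ci, chrom in enumerate(grid.genome.chrom_names):
        mask = grid.chroms == ci
        if not mask.any():
            continue
        area = track.integral(chrom, grid.starts[mask], grid.ends[mask])
        values[mask] = area / (grid.ends[mask] - grid.starts[mask])
    return BinSignal(grid, values, label)


def rpgc_normalize(
    track: CoverageTrack, effective_genome_size: int | None = None,
    scale_factor: float = 1.0,
) -> CoverageTrack:
    """1× (reads-per-genomic-content) normalization.

    Rescales so the length-weighted mean coverage over the effective genome
    equals ``scale_factor``. The scale factor carries any external (e.g.
    spike-in derived) calibration; it is a config input here.
    """
    if effective_genome_size is None:
        effective_genome_size = track.genome.effective_genome_size
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be positive")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    total = track.total_signal()
    if total == 0:
        raise ValueError("empty signal: cannot normalize an all-zero track")
    return track.scale(effective_genome_size / total * scale_factor)


def step_averages(track: CoverageTrack, chrom: str, start: int, end: int,
                  step: int = 100) -> np.ndarray:
    """Averages over the genome-aligned ``step``-bp windows overlapping [start, end).

    Windows are anchored at multiples of ``step`` (the fixed-bin convention of
    coverage bigWigs); each average is taken over the full window, clipped at
    the chromosome end.
    """
    length = track.genome.length_of(chrom)
    first = (start // step) * step
    edges = np.arange(first, end, step, dtype=np.int64)
    win_end = np.minimum(edges + step, length)
    area = track.integral(chrom, edges, win_end)
    return area / (win_end - edges)


def peak_intensity(track: CoverageTrack, peaks: list[Peak], step: int = 100) -> np.ndarray:
    """Per-peak intensity: mean of the five largest step averages in the peak.

    Peaks spanning fewer than five steps use all available steps. Reading the
    signal at step (default 100 bp) resolution mirrors intensity extraction
    from fixed-bin normalized coverage tracks.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    out = np.empty(len(peaks))
    for i, p in enumerate(peaks):
        vals = step_averages(track, p.chrom, p.start, p.end, step)
        k = min(5, len(vals))
        top = np.partition(vals, len(vals) - k)[-k:]
        out[i] = top.mean()
    return out


def log2_signal(values, pseudocount: float = 0.01) -> np.ndarray:
    """Elementwise log2(v + pseudocount); the pseudocount bounds zero bins."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative input to log2_signal")
    return np.log2(values + pseudocount)


def anchor_matrix(
    track: CoverageTrack,
    anchors: list[tuple[str, int]],
    flank: int = 5000,
    step: int = 100,
) -> AnchorMatrix:
    """Signal matrix around single-bp anchors (peak summits or TSS).

    Cell (i, j) is the step-average of the track over
    [anchor_i + offset_j, anchor_i + offset_j + step); windows beyond a
    chromosome end contribute 0 (zero-padding keeps the anchor/row bijection).
    """
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    offsets = np.arange(-flank, flank, step, dtype=np.int64)
    matrix = np.zeros((len(anchors), len(offsets)))
    n_clipped = 0
    for i, (chrom, pos) in enumerate(anchors):
        length = track.genome.length_of(chrom)
        w_start = pos + offsets
        w_end = w_start + step
        if w_start[0] < 0 or w_end[-1] > length:
            n_clipped += 1
        qs = np.clip(w_start, 0, length)
        qe = np.clip(w_end, 0, length)
        area = track.integral(chrom, qs, qe)
        matrix[i] = area / step  # clipped portion counts as zero signal
    return AnchorMatrix(offsets, step, matrix, n_clipped)


def metaprofile(matrix: AnchorMatrix) -> np.ndarray:
    """Column means of an anchor matrix (the metaplot profile)."""
    return matrix.matrix.mean(axis=0)


def bin_correlation(
    signal_a: BinSignal, signal_b: BinSignal, pseudocount: float = 0.01
) -> tuple[float, int]:
    """Pearson r between two bin signals on log2(value + pseudocount) scale.

    Returns (r, number of bins used).
    """
    if signal_a.grid is not signal_b.grid and (
        signal_a.grid.bin_size != signal_b.grid.bin_size
        or signal_a.grid.genome != signal_b.grid.genome
    ):
        raise ValueError("bin signals are on different grids")
    a = log2_signal(signal_a.values, pseudocount)
    b = log2_signal(signal_b.values, pseudocount)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: zero variance in a signal")
    r, _ = stats.pearsonr(a, b)
    return float(r), len(a)


def call_simple_peaks(
    track: CoverageTrack,
    threshold: float,
    min_len: int = 200,
    merge_gap: int = 0,
    step: int = 100,
) -> list[Peak]:
    """Threshold peak caller (plumbing; not a MACS2/SPP replacement).

    Maximal runs of step windows with average ≥ threshold, gaps ≤ merge_gap
    merged, regions ≥ min_len kept. Summit = leftmost maximal step midpoint.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks: list[Peak] = []
    for chrom in track.genome.chrom_names:
        length = track.genome.length_of(chrom)
        vals = step_averages(track, chrom, 0, length, step)
        above = vals >= threshold
        if not above.any():
            continue
        # contiguous above-threshold step runs
        idx = np.nonzero(above)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # exclusive, steps
        regions = [(int(s) * step, min(int(e) * step, length))
                   for s, e in zip(run_starts, run_ends)]
        # merge across small gaps
        merged = [list(regions[0])]
        for s, e in regions[1:]:
            if s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for n, (s, e) in enumerate(merged):
            if e - s < min_len:
                continue
            region_vals = vals[s // step : (e + step - 1) // step]
            best = int(np.argmax(region_vals))  # argmax is leftmost on ties
            summit_abs = min(s + best * step + step // 2, e - 1)
            peaks.append(
                Peak(
                    Interval(chrom, s, e),
                    name=f"{chrom}_peak{n}",
                    score=float(region_vals.max()),
                    summit_offset=summit_abs - s,
                    source_format="narrowPeak",
                )
            )
    return peaks


def filter_blacklist(intervals, blacklist) -> list:
    """Drop peaks/intervals overlapping any blacklist interval by ≥ 1 bp."""
    black = list(blacklist)
    out = []
    for item in intervals:
        iv = item.interval if isinstance(item, Peak) else item
        if not any(iv.overlaps(b.interval if isinstance(b, Peak) else b) for b in black):
            out.append(item)
    return out
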