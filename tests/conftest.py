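import numpy as np
import pytest

from ubredist.genome_io import CoverageTrack, Genome, Interval, Peak
from ubredist.synthetic import SimConfig, simulate_genome, simulate_peak_calls, simulate_tracks


@pytest.fixture
def tiny_genome():
    return Genome(("chr1", "chr2"), (10_000, 8_000))


def random_track(genome: Genome, rng: np.random.Generator, max_runs: int = 30) -> CoverageTrack:
    """Random valid coverage track: sorted, non-overlapping, non-negative runs."""
    runs = {}
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n = int(rng.integers(0, max_runs))
        if n == 0:
            continue
        cuts = np.sort(rng.choice(length, size=2 * n, replace=False))
        starts, ends = cuts[0::2], cuts[1::2]
        values = rng.uniform(0, 10, size=n)
        runs[chrom] = (starts, ends, values)
    return CoverageTrack(genome, runs)


def per_base(track: CoverageTrack, chrom: str) -> np.ndarray:
    """Dense per-base expansion of a track — the brute-force oracle substrate."""
    arr = np.zeros(track.genome.length_of(chrom))
    s, e, v = track.runs.get(chrom, (np.array([], dtype=int),) * 2 + (np.array([]),))
    for i in range(len(s)):
        arr[s[i]:e[i]] = v[i]
    return arr


def make_peak(chrom, start, end, name=".", summit=None):
    return Peak(Interval(chrom, start, end), name=name, summit_offset=summit,
                source_format="narrowPeak" if summit is not None else "bed3")


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation, shared across tests (deterministic, seed 1)."""
    config = SimConfig(seed=1)
    genome, tss = simulate_genome(config)
    tracks, truth = simulate_tracks(config, genome, tss)
    peaks = simulate_peak_calls(truth)
    return {"config": config, "genome": genome, "tss": tss,
            "tracks": tracks, "truth": truth, "peaks": peaks}
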