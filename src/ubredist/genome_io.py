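"""Genomic domain types and plain-text format I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based annotation input is converted at the reader boundary.
Supported formats: chrom.sizes, BED3/BED6, ENCODE narrowPeak/broadPeak,
bedGraph, GMT gene sets, and TSV count/design tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "Interval",
    "Peak",
    "CoverageTrack",
    "TSSRecord",
    "CountMatrix",
    "FormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_tss",
    "write_tss",
    "read_counts",
    "read_gmt",
    "write_table",
]

PEAK_FORMATS = ("bed3", "bed6", "narrowPeak", "broadPeak")


class FormatError(ValueError):
    """A file violated the expected format; message names the offending line."""


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths.

    ``effective_genome_size`` is the mappable-genome scalar used by RPGC
    normalization (for mouse GRCm38 the conventional value is
    2_494_787_188 bp); it defaults to the summed chromosome lengths.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    effective_genome_size: int = 0

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names/lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.effective_genome_size <= 0:
            object.__setattr__(
                self, "effective_genome_size", int(sum(self.chrom_lengths))
            )

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak. ``summit_offset`` is bp from ``start`` or None (absent).

    narrowPeak column 10 carries the summit; the ENCODE convention maps the
    sentinel −1 to absent.
    """

    interval: Interval
    name: str = "."
    score: float = 0.0
    summit_offset: int | None = None
    source_format: str = "bed3"

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("peak score must be non-negative")
        if self.summit_offset is not None:
            if not (0 <= self.summit_offset < len(self.interval)):
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak "
                    f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


class CoverageTrack:
    """Piecewise-constant non-negative signal over a genome (bedGraph semantics).

    Runs are stored per chromosome as parallel numpy arrays
    ``(starts, ends, values)``, sorted and non-overlapping; uncovered
    positions carry an implicit value of 0.
    """

    def __init__(
        self,
        genome: Genome,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ):
        self.genome = genome
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in (runs or {}).items():
            self._set_runs(chrom, np.asarray(s), np.asarray(e), np.asarray(v))
        self._cum: dict[str, np.ndarray] = {}

    def _set_runs(self, chrom, starts, ends, values):
        if chrom not in self.genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        order = np.argsort(starts, kind="stable")
        starts = np.asarray(starts, dtype=np.int64)[order]
        ends = np.asarray(ends, dtype=np.int64)[order]
        values = np.asarray(values, dtype=float)[order]
        if np.any(values < 0):
            raise ValueError(f"negative coverage value on {chrom}")
        if np.any(starts >= ends):
            raise ValueError(f"empty or inverted run on {chrom}")
        if len(ends) and ends[-1] > self.genome.length_of(chrom):
            raise ValueError(f"run past end of {chrom}")
        if len(starts) > 1:
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if len(bad):
                i = bad[0]
                raise ValueError(
                    f"overlapping runs on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
        # drop zero-value runs: implicit zeros make them redundant
        keep = values > 0
        self.runs[chrom] = (starts[keep], ends[keep], values[keep])

    def _cumulative(self, chrom):
        """Prefix integrals of runs (for O(log n) area queries)."""
        if chrom not in self._cum:
            s, e, v = self.runs.get(chrom, (np.array([]),) * 3)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])
        return self._cum[chrom]

    def integral(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized ∫ value dx over [start, end) queries on one chromosome."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        s, e, v = self.runs.get(chrom, (np.array([], dtype=np.int64),) * 2 + (np.array([]),))
        if len(s) == 0:
            return np.zeros(len(starts))
        cum = self._cumulative(chrom)

        def F(x):
            j = np.searchsorted(s, x, side="right") - 1
            j_safe = np.clip(j, 0, len(s) - 1)
            partial = v[j_safe] * np.clip(x - s[j_safe], 0, e[j_safe] - s[j_safe])
            out = cum[j_safe] + partial
            return np.where(j < 0, 0.0, out)

        return F(ends) - F(starts)

    def total_signal(self) -> float:
        """Σ value · bp over the whole track."""
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self.runs.values())
        )

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self.runs.items()},
        )

    def canonical_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Runs with adjacent equal-valued runs merged (canonical form)."""
        s, e, v = self.runs.get(chrom, (np.array([], dtype=np.int64),) * 2 + (np.array([]),))
        if len(s) == 0:
            return s, e, v
        keep = np.ones(len(s), dtype=bool)
        out_s, out_e, out_v = [s[0]], [e[0]], [v[0]]
        for i in range(1, len(s)):
            if s[i] == out_e[-1] and v[i] == out_v[-1]:
                out_e[-1] = e[i]
            else:
                out_s.append(s[i])
                out_e.append(e[i])
                out_v.append(v[i])
        del keep
        return (np.array(out_s), np.array(out_e), np.array(out_v))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.genome != other.genome:
            return False
        for chrom in self.genome.chrom_names:
            a = self.canonical_runs(chrom)
            b = other.canonical_runs(chrom)
            if any(len(x) != len(y) for x, y in zip(a, b)):
                return False
            if not all(np.allclose(x, y) for x, y in zip(a, b)):
                return False
        return True


@dataclass
class CountMatrix:
    """Gene × sample integer counts with a sample design table.

    ``design`` is indexed by sample id with columns
    ``condition``, ``stage``, ``replicate``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    design: pd.DataFrame

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape inconsistent with ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = set(self.sample_ids) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    def samples_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        for key, val in criteria.items():
            mask &= self.design[key] == val
        return [s for s in self.sample_ids if s in self.design.index[mask]]

    def submatrix(self, samples: Sequence[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in samples]
        return self.counts[:, idx]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path, effective_genome_size: int = 0) -> Genome:
    """Parse a two-column (name, length) chrom.sizes file."""
    names, lengths = [], []
    for lineno, line in _lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        name, length = fields[0], fields[1]
        if name in names:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        try:
            length = int(length)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length {length!r}") from None
        if length <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive length {length}")
        names.append(name)
        lengths.append(length)
    if not names:
        raise FormatError(f"{path}: no chromosomes")
    return Genome(tuple(names), tuple(lengths), effective_genome_size)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_peaks(path, format: str, genome: Genome | None = None) -> list[Peak]:
    """Read BED3/BED6/narrowPeak/broadPeak peak calls.

    Peaks on chromosomes absent from ``genome`` (when supplied) are dropped
    with a logged count, not a failure — annotation files routinely include
    scaffolds.
    """
    if format not in PEAK_FORMATS:
        raise ValueError(f"unknown peak format {format!r}; expected one of {PEAK_FORMATS}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "broadPeak": 9}[format]
    peaks: list[Peak] = []
    dropped = 0
    for lineno, line in _lines(path):
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < min_cols:
            raise FormatError(f"{path}:{lineno}: {format} needs ≥{min_cols} columns")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start ≥ end ({start} ≥ {end})")
        if genome is not None and chrom not in genome:
            dropped += 1
            continue
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
        summit = None
        if format == "narrowPeak":
            s10 = int(f[9])
            summit = s10 if s10 >= 0 else None
        peaks.append(
            Peak(Interval(chrom, start, end), name=name, score=score,
                 summit_offset=summit, source_format=format)
        )
    if dropped:
        logger.warning("%s: dropped %d peaks on chromosomes outside the genome", path, dropped)
    return peaks


def write_peaks(peaks: Iterable[Peak], path, format: str = "narrowPeak") -> None:
    if format not in PEAK_FORMATS:
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            base = [p.chrom, str(p.start), str(p.end)]
            if format == "bed3":
                fh.write("\t".join(base) + "\n")
                continue
            base += [p.name, f"{p.score:g}", "."]
            if format == "bed6":
                fh.write("\t".join(base) + "\n")
                continue
            base += ["0", "-1", "-1"]
            if format == "narrowPeak":
                base.append(str(p.summit_offset if p.summit_offset is not None else -1))
            fh.write("\t".join(base) + "\n")


def read_bedgraph(path, genome: Genome) -> CoverageTrack:
    """Read a 4-column bedGraph; rows may be unsorted, overlaps are an error."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    dropped = 0
    for lineno, line in _lines(path):
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative value {value}")
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start ≥ end")
        if chrom not in genome:
            dropped += 1
            continue
        per_chrom.setdefault(chrom, []).append((start, end, value))
    if dropped:
        logger.warning("%s: dropped %d rows on chromosomes outside the genome", path, dropped)
    runs = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(rows)
        runs[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    try:
        return CoverageTrack(genome, runs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write canonical (sorted, merged, zero-suppressed) bedGraph rows."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            s, e, v = track.canonical_runs(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")


def read_tss(path, genome: Genome | None = None) -> list[TSSRecord]:
    """Read BED6 gene records; TSS = start on '+', end − 1 on '−'."""
    records: list[TSSRecord] = []
    seen: set[str] = set()
    dropped = 0
    for lineno, line in _lines(path):
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
        chrom, start, end, gene_id, _score, strand = f[:6]
        start, end = int(start), int(end)
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        if genome is not None and chrom not in genome:
            dropped += 1
            continue
        seen.add(gene_id)
        tss = start if strand == "+" else end - 1
        records.append(TSSRecord(gene_id, chrom, tss, strand))
    if dropped:
        logger.warning("%s: dropped %d genes on chromosomes outside the genome", path, dropped)
    return records


def write_tss(records: Iterable[TSSRecord], path, gene_length: int = 1000) -> None:
    """Write TSS records as BED6 single-TSS gene stubs (round-trips the TSS)."""
    with open(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                start, end = r.tss, r.tss + gene_length
            else:
                start, end = max(0, r.tss + 1 - gene_length), r.tss + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_counts(path, design_path) -> CountMatrix:
    """Read a gene × sample TSV count matrix and its sample design TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    for col in ("condition", "stage", "replicate"):
        if col not in design.columns:
            raise FormatError(f"{design_path}: design lacks column {col!r}")
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise FormatError(f"{path}: counts must be non-negative integers")
    return CountMatrix(
        gene_ids=list(table.index.astype(str)),
        sample_ids=list(table.columns.astype(str)),
        counts=counts.astype(np.int64),
        design=design,
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: GMT needs ≥3 columns")
        sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_table(df: pd.DataFrame, path, comments: dict | None = None) -> None:
    """Write a result table as TSV with ``# key: value`` header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
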