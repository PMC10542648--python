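"""Peak annotation relative to TSS and gene features, and peak-set overlaps.

Region classes follow the summit-distance convention: a peak whose summit
lies within 2.5 kb of a TSS is a promoter peak; a summit ≥ 3 kb from every
TSS is a non-promoter peak. Summits falling in the (2.5 kb, 3 kb) gap are an
explicit ``ambiguous`` class, excluded from promoter/non-promoter contrasts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import Interval, Peak, TSSRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PeakLabel",
    "OverlapPartition",
    "summit_of",
    "classify_region",
    "classify_feature",
    "overlap_partition",
    "binding_frequency",
    "labels_to_frame",
]

REGION_CLASSES = ("promoter", "non_promoter", "ambiguous")
FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class PeakLabel:
    peak: Peak
    summit_pos: int
    tss_distance: int  # signed; negative = summit upstream of the nearest TSS
    nearest_gene: str
    region_class: str
    feature_class: str | None = None


@dataclass
class OverlapPartition:
    unique_a: list[Peak]
    shared_a: list[Peak]
    unique_b: list[Peak]
    shared_b: list[Peak]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unique_a": len(self.unique_a),
            "shared_a": len(self.shared_a),
            "unique_b": len(self.unique_b),
            "shared_b": len(self.shared_b),
        }


def summit_of(peak: Peak) -> int:
    """Absolute summit position; midpoint when the format carries no summit."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def _signed_distance(summit: int, rec: TSSRecord) -> int:
    # upstream (5' of the TSS on the gene's strand) is negative
    if rec.strand == "+":
        return summit - rec.tss
    return rec.tss - summit


def classify_region(
    peaks: list[Peak],
    tss_records: list[TSSRecord],
    promoter_radius: int = 2500,
    nonpromoter_min: int = 3000,
) -> list[PeakLabel]:
    """Label each peak promoter / non_promoter / ambiguous by summit–TSS distance.

    A summit equidistant from two TSS takes the upstream one (negative signed
    distance); ties are logged. Ambiguous peaks (distance in the open gap
    between the two radii) are counted in the log.
    """
    if not tss_records:
        raise ValueError("empty TSS list")
    if not (0 < promoter_radius <= nonpromoter_min):
        raise ValueError("need 0 < promoter_radius <= nonpromoter_min")

    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss_records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    positions = {
        chrom: (np.array([r.tss for r in sorted(recs, key=lambda r: r.tss)]),
                sorted(recs, key=lambda r: r.tss))
        for chrom, recs in by_chrom.items()
    }

    labels: list[PeakLabel] = []
    n_ties = 0
    n_ambiguous = 0
    for peak in peaks:
        summit = summit_of(peak)
        if peak.chrom not in positions:
            labels.append(PeakLabel(peak, summit, 2**62, "", "non_promoter"))
            continue
        pos, recs = positions[peak.chrom]
        j = np.searchsorted(pos, summit)
        candidates = [recs[k] for k in (j - 1, j) if 0 <= k < len(recs)]
        dists = [abs(summit - r.tss) for r in candidates]
        best = int(np.argmin(dists))
        if len(candidates) == 2 and dists[0] == dists[1]:
            n_ties += 1
            signed = [_signed_distance(summit, r) for r in candidates]
            best = int(np.argmin(signed))  # upstream (more negative) wins
        rec = candidates[best]
        d = _signed_distance(summit, rec)
        if abs(d) <= promoter_radius:
            cls = "promoter"
        elif abs(d) >= nonpromoter_min:
            cls = "non_promoter"
        else:
            cls = "ambiguous"
            n_ambiguous += 1
        labels.append(PeakLabel(peak, summit, d, rec.gene_id, cls))
    if n_ties:
        logger.info("classify_region: %d equidistant-TSS ties resolved upstream", n_ties)
    if n_ambiguous:
        logger.info(
            "classify_region: %d peaks in the (%d, %d) ambiguous gap excluded "
            "from promoter/non-promoter contrasts",
            n_ambiguous, promoter_radius, nonpromoter_min,
        )
    return labels


def classify_feature(
    labels: list[PeakLabel],
    gene_spans: list[Interval],
    exons: list[Interval],
) -> tuple[list[PeakLabel], dict[str, float]]:
    """Assign promoter > exon > intron > intergenic at the summit position.

    The promoter call is taken from the TSS-distance label; the gene model
    supplies gene spans and exon intervals for the remaining classes.
    Returns the labels (mutated in place) and class proportions summing to 1.
    """
    gene_trees: dict[str, IntervalTree] = {}
    for iv in gene_spans:
        gene_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    exon_trees: dict[str, IntervalTree] = {}
    for iv in exons:
        exon_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    for lab in labels:
        s = lab.summit_pos
        chrom = lab.peak.chrom
        if lab.region_class == "promoter":
            lab.feature_class = "promoter"
        elif chrom in exon_trees and exon_trees[chrom].overlaps(s, s + 1):
            lab.feature_class = "exon"
        elif chrom in gene_trees and gene_trees[chrom].overlaps(s, s + 1):
            lab.feature_class = "intron"
        else:
            lab.feature_class = "intergenic"
    counts = Counter(lab.feature_class for lab in labels)
    total = max(1, len(labels))
    proportions = {cls: counts.get(cls, 0) / total for cls in FEATURE_CLASSES}
    return labels, proportions


def _tree_of(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _overlaps_by(trees: dict[str, IntervalTree], peak: Peak, min_bp: int) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(peak.start, peak.end):
        if min(peak.end, hit.end) - max(peak.start, hit.begin) >= min_bp:
            return True
    return False


def overlap_partition(
    peaks_a: list[Peak], peaks_b: list[Peak], min_overlap_bp: int = 1
) -> OverlapPartition:
    """Venn partition of two peak sets by ≥ min_overlap_bp interval overlap.

    Shared counts are reported per side: a peak is shared iff it overlaps at
    least one peak of the other set, so the two shared counts may differ.
    """
    trees_a, trees_b = _tree_of(peaks_a), _tree_of(peaks_b)
    unique_a, shared_a, unique_b, shared_b = [], [], [], []
    for p in peaks_a:
        (shared_a if _overlaps_by(trees_b, p, min_overlap_bp) else unique_a).append(p)
    for p in peaks_b:
        (shared_b if _overlaps_by(trees_a, p, min_overlap_bp) else unique_b).append(p)
    return OverlapPartition(unique_a, shared_a, unique_b, shared_b)


def binding_frequency(
    peaks_by_cluster: dict, ring1b_peaks: list[Peak], min_overlap_bp: int = 1
) -> dict:
    """Per-cluster fraction of peaks overlapping ≥ 1 partner (e.g. RING1B) peak.

    Empty clusters yield None (frequency undefined). Returns
    {cluster: {"frequency": float | None, "n": int}}.
    """
    trees = _tree_of(ring1b_peaks)
    out = {}
    for cluster, peaks in peaks_by_cluster.items():
        n = len(peaks)
        if n == 0:
            out[cluster] = {"frequency": None, "n": 0}
            continue
        hits = sum(_overlaps_by(trees, p, min_overlap_bp) for p in peaks)
        out[cluster] = {"frequency": hits / n, "n": n}
    return out


def classify_bin_regions(
    grid,
    tss_records: list[TSSRecord],
    promoter_radius: int = 2500,
    nonpromoter_min: int = 3000,
) -> np.ndarray:
    """Promoter / non_promoter / ambiguous label per bin, by bin midpoint.

    Applies the same summit-distance rule as :func:`classify_region` with the
    bin midpoint standing in for the summit.
    """
    if not tss_records:
        raise ValueError("empty TSS list")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for rec in tss_records:
        pos_by_chrom.setdefault(rec.chrom, []).append(rec.tss)
    pos_by_chrom = {c: np.sort(np.array(p)) for c, p in pos_by_chrom.items()}
    mids = grid.midpoints()
    out = np.full(grid.n_bins, "non_promoter", dtype=object)
    for ci, chrom in enumerate(grid.genome.chrom_names):
        mask = grid.chroms == ci
        if not mask.any() or chrom not in pos_by_chrom:
            continue
        pos = pos_by_chrom[chrom]
        m = mids[mask]
        j = np.clip(np.searchsorted(pos, m), 1, len(pos) - 1) if len(pos) > 1 else np.zeros(len(m), dtype=int)
        if len(pos) > 1:
            dist = np.minimum(np.abs(m - pos[j - 1]), np.abs(m - pos[j]))
        else:
            dist = np.abs(m - pos[0])
        cls = np.full(len(m), "ambiguous", dtype=object)
        cls[dist <= promoter_radius] = "promoter"
        cls[dist >= nonpromoter_min] = "non_promoter"
        out[mask] = cls
    return out


def labels_to_frame(labels: list[PeakLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [l.peak.chrom for l in labels],
            "start": [l.peak.start for l in labels],
            "end": [l.peak.end for l in labels],
            "name": [l.peak.name for l in labels],
            "summit": [l.summit_pos for l in labels],
            "tss_distance": [l.tss_distance for l in labels],
            "nearest_gene": [l.nearest_gene for l in labels],
            "region_class": [l.region_class for l in labels],
            "feature_class": [l.feature_class or "" for l in labels],
        }
    )
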