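"""Differential-occupancy core.

Four analyses built on normalized peak densities and 2-kb bin signals:

* **Quantile clusters** (C1–C4): rank quartiles of non-promoter H2AK119ub1
  peak intensity, low to high, with coordinate tie-breaks.
* **M-value analysis**: per-peak M = log2 density ratio and A = mean log2
  density between two conditions; an ordinary least-squares M ~ A line fitted
  on common peaks rescales all peaks so that condition-wide systematic trends
  (global scaling, intensity-dependent bias) are removed, after which a
  conditional binomial test scores per-peak significance. The line is fitted
  robustly (Huber loss) so that a genuinely changed minority of common peaks
  does not tilt it.
* **Bin change classes**: per-bin log2 fold changes of two marks (KO vs WT)
  classified as both_up / both_down / discordant / unchanged.
* **Promoter change classes**: promoter peaks called unchanged
  (M ∈ [−0.5, 0.5]), lost (M < −1.5) or other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import Peak
from .signals import BinSignal

__all__ = [
    "ClusterAssignment",
    "MAResult",
    "BinChangeTable",
    "quantile_clusters",
    "cluster_signal_test",
    "ma_normalize",
    "bin_change_classify",
    "promoter_change_classes",
    "frequency_vs_level_report",
]

CHANGE_CLASSES = ("both_up", "both_down", "discordant", "unchanged")
PROMOTER_CLASSES = ("unchanged", "lost", "other")


@dataclass
class ClusterAssignment:
    """Peak → C1..Ck rank-quantile labels; C1 lowest intensity."""

    labels: list[str]
    boundaries: np.ndarray  # intensity at the k−1 cut points
    order: np.ndarray  # permutation sorting peaks by (intensity, coordinate)

    def members(self, cluster: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab == cluster], dtype=np.intp
        )

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.labels), key=lambda c: int(c[1:]))


@dataclass
class MAResult:
    """Per-peak M/A values with rescaling fit and significance."""

    table: pd.DataFrame  # columns: side, d_a, d_b, m_raw, a, m_rescaled, p_value, padj
    slope: float
    intercept: float
    pseudocount: float

    @property
    def common(self) -> pd.DataFrame:
        return self.table[self.table["side"] == "common"]


@dataclass
class BinChangeTable:
    table: pd.DataFrame  # columns: delta_mark1, delta_mark2, change_class, region_class
    delta: float

    def proportions(self, by_region: bool = False) -> pd.DataFrame:
        """Class proportions overall or stratified by region class (each row sums to 1)."""
        if by_region:
            counts = (
                self.table.groupby(["region_class", "change_class"], observed=False)
                .size()
                .unstack(fill_value=0)
            )
        else:
            counts = self.table["change_class"].value_counts().to_frame().T
        for cls in CHANGE_CLASSES:
            if cls not in counts.columns:
                counts[cls] = 0
        counts = counts[list(CHANGE_CLASSES)]
        return counts.div(counts.sum(axis=1), axis=0)


def quantile_clusters(
    intensities: np.ndarray,
    peaks: list[Peak] | None = None,
    k: int = 4,
) -> ClusterAssignment:
    """Rank-based k-quantile clusters of peak intensity (C1 low … Ck high).

    Ties in intensity are broken by genomic coordinate (chromosome order,
    then start) when peaks are supplied, by index otherwise, so the
    assignment is deterministic. Cluster sizes differ by at most one; when n
    is not divisible by k the lower clusters take the extra peaks.
    """
    intensities = np.asarray(intensities, dtype=float)
    n = len(intensities)
    if n < k:
        raise ValueError(f"need at least k={k} peaks, got {n}")
    if peaks is not None:
        chrom_order = sorted({p.chrom for p in peaks})
        chrom_rank = {c: i for i, c in enumerate(chrom_order)}
        keys = np.lexsort(
            (
                np.array([p.start for p in peaks]),
                np.array([chrom_rank[p.chrom] for p in peaks]),
                intensities,
            )
        )
    else:
        keys = np.argsort(intensities, kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    labels = [""] * n
    boundaries = []
    pos = 0
    for ci, size in enumerate(sizes):
        for idx in keys[pos : pos + size]:
            labels[idx] = f"C{ci + 1}"
        pos += size
        if ci < k - 1:
            boundaries.append(intensities[keys[pos - 1]])
    return ClusterAssignment(labels, np.array(boundaries), keys)


def cluster_signal_test(values_by_cluster: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests across clusters, BH-adjusted.

    Returns one row per cluster pair with p_value and padj (BH across the
    whole reported family).
    """
    for cluster, vals in values_by_cluster.items():
        if len(vals) < 3:
            raise ValueError(f"cluster {cluster} has fewer than 3 values")
    names = list(values_by_cluster)
    rows = []
    for a, b in combinations(names, 2):
        res = stats.mannwhitneyu(
            values_by_cluster[a], values_by_cluster[b], alternative="two-sided"
        )
        rows.append(
            {
                "cluster_a": a,
                "cluster_b": b,
                "n_a": len(values_by_cluster[a]),
                "n_b": len(values_by_cluster[b]),
                "median_a": float(np.median(values_by_cluster[a])),
                "median_b": float(np.median(values_by_cluster[b])),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def ma_normalize(
    density_a: np.ndarray,
    density_b: np.ndarray,
    side: np.ndarray,
    pseudocount: float = 0.01,
    peak_lengths: np.ndarray | None = None,
    step: int = 100,
    min_common: int = 10,
) -> MAResult:
    """M-value normalization of paired peak densities between two conditions.

    M = log2((dA + pc) / (dB + pc)), A = 0.5·log2((dA + pc)(dB + pc)).
    An OLS line M = a + b·A is fitted on **common** peaks only and subtracted
    from every peak (common and unique), extrapolating the systematic trend
    to condition-unique peaks. Significance is a two-sided conditional
    binomial test of the rescaled step-count equivalents xA vs xA + xB at
    p = 0.5 (densities × peak steps, after moving the fitted trend onto
    side B), with BH adjustment across all peaks.

    ``side`` entries must be one of {"common", "unique_a", "unique_b"}.
    """
    density_a = np.asarray(density_a, dtype=float)
    density_b = np.asarray(density_b, dtype=float)
    side = np.asarray(side)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bad = set(side) - {"common", "unique_a", "unique_b"}
    if bad:
        raise ValueError(f"unknown side labels: {sorted(bad)}")
    da = density_a + pseudocount
    db = density_b + pseudocount
    if np.any(da <= 0) or np.any(db <= 0):
        raise ValueError("densities must be non-negative")
    m_raw = np.log2(da / db)
    a_val = 0.5 * np.log2(da * db)
    is_common = side == "common"
    n_common = int(is_common.sum())
    if n_common < min_common:
        raise ValueError(
            f"only {n_common} common peaks (< {min_common}); refusing to fit"
        )
    # robust (Huber) line: the rescaling must track the unchanged majority of
    # common peaks, not be tilted by a genuinely changed minority
    a_common, m_common = a_val[is_common], m_raw[is_common]
    if np.ptp(a_common) < 1e-12 or np.ptp(m_common) < 1e-12:
        slope, intercept = 0.0, float(np.median(m_common))
    else:
        import statsmodels.api as sm

        design = sm.add_constant(a_common)
        fit = sm.RLM(m_common, design, M=sm.robust.norms.HuberT()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    trend = intercept + slope * a_val
    m_rescaled = m_raw - trend

    # count equivalents: density × number of steps, trend moved onto side B
    if peak_lengths is None:
        n_steps = np.full(len(da), 20.0)
    else:
        n_steps = np.maximum(1.0, np.asarray(peak_lengths, dtype=float) / step)
    db_adj = db * np.power(2.0, trend)
    x_a = np.rint(da * n_steps).astype(np.int64)
    x_b = np.rint(db_adj * n_steps).astype(np.int64)
    p_values = np.ones(len(da))
    for i in range(len(da)):
        n_tot = x_a[i] + x_b[i]
        if n_tot == 0:
            continue
        p_values[i] = stats.binomtest(int(x_a[i]), int(n_tot), 0.5).pvalue
    padj = multipletests(p_values, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "side": side,
            "d_a": density_a,
            "d_b": density_b,
            "m_raw": m_raw,
            "a": a_val,
            "m_rescaled": m_rescaled,
            "p_value": p_values,
            "padj": padj,
        }
    )
    return MAResult(table, float(slope), float(intercept), pseudocount)


def bin_change_classify(
    mark1_ko: BinSignal,
    mark1_wt: BinSignal,
    mark2_ko: BinSignal,
    mark2_wt: BinSignal,
    delta: float = 0.5,
    pseudocount: float = 0.01,
    region_class: np.ndarray | None = None,
) -> BinChangeTable:
    """Classify simultaneous per-bin changes of two marks (KO vs WT).

    Per bin, Δ = log2((KO + pc)/(WT + pc)) for each mark; both_up iff both
    Δ > delta, both_down iff both Δ < −delta, unchanged iff both |Δ| ≤ delta,
    discordant otherwise. ``delta=0`` degenerates to sign-only concordance.
    """
    grids = {id(s.grid) for s in (mark1_ko, mark1_wt, mark2_ko, mark2_wt)}
    if len(grids) > 1:
        ref = mark1_ko.grid
        for s in (mark1_wt, mark2_ko, mark2_wt):
            if (
                s.grid.bin_size != ref.bin_size
                or s.grid.genome != ref.genome
                or s.grid.n_bins != ref.n_bins
            ):
                raise ValueError("bin signals are on different grids")
    d1 = np.log2(mark1_ko.values + pseudocount) - np.log2(mark1_wt.values + pseudocount)
    d2 = np.log2(mark2_ko.values + pseudocount) - np.log2(mark2_wt.values + pseudocount)
    cls = np.full(len(d1), "discordant", dtype=object)
    cls[(d1 > delta) & (d2 > delta)] = "both_up"
    cls[(d1 < -delta) & (d2 < -delta)] = "both_down"
    cls[(np.abs(d1) <= delta) & (np.abs(d2) <= delta)] = "unchanged"
    table = pd.DataFrame(
        {
            "chrom": [mark1_ko.grid.genome.chrom_names[c] for c in mark1_ko.grid.chroms],
            "start": mark1_ko.grid.starts,
            "end": mark1_ko.grid.ends,
            "delta_mark1": d1,
            "delta_mark2": d2,
            "change_class": cls,
            "region_class": region_class if region_class is not None else "all",
        }
    )
    return BinChangeTable(table, delta)


def promoter_change_classes(
    m_values: np.ndarray,
    unchanged_band: tuple[float, float] = (-0.5, 0.5),
    lost_cut: float = -1.5,
) -> pd.DataFrame:
    """Call promoter peaks unchanged / lost / other from rescaled M values.

    unchanged: M ∈ [band_lo, band_hi]; lost: M < lost_cut; other: the rest.
    Classes are disjoint and exhaustive (requires lost_cut < band_lo).
    """
    lo, hi = unchanged_band
    if not (lost_cut < lo < hi):
        raise ValueError("need lost_cut < band_lo < band_hi")
    m_values = np.asarray(m_values, dtype=float)
    cls = np.full(len(m_values), "other", dtype=object)
    cls[(m_values >= lo) & (m_values <= hi)] = "unchanged"
    cls[m_values < lost_cut] = "lost"
    return pd.DataFrame({"m": m_values, "change_class": cls})


def frequency_vs_level_report(
    assignment: ClusterAssignment,
    frequencies: dict,
    h2aub_intensity: np.ndarray,
    ring1b_density: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-cluster summary joining intensity, partner density and binding frequency.

    Returns (table, Spearman ρ of cluster index vs binding frequency). With
    k = 4 clusters ρ is coarse (only 4 ranks); it is reported, not tested.
    """
    h2aub_intensity = np.asarray(h2aub_intensity, dtype=float)
    rows = []
    for cluster in assignment.clusters:
        idx = assignment.members(cluster)
        freq = frequencies.get(cluster, {}).get("frequency")
        row = {
            "cluster": cluster,
            "n": len(idx),
            "mean_intensity": float(h2aub_intensity[idx].mean()) if len(idx) else np.nan,
            "median_intensity": float(np.median(h2aub_intensity[idx])) if len(idx) else np.nan,
            "binding_frequency": freq,
        }
        if ring1b_density is not None:
            row["mean_ring1b_density"] = float(np.asarray(ring1b_density)[idx].mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["binding_frequency"].notna()
    if ok.sum() >= 2 and table.loc[ok, "binding_frequency"].nunique() > 1:
        rho = float(
            stats.spearmanr(
                np.arange(len(table))[ok], table.loc[ok, "binding_frequency"]
            ).statistic
        )
    else:
        rho = float("nan")
    return table, rho
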