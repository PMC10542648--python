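"""Expression-side analysis.

A self-contained negative-binomial differential-expression test (median-of-
ratios normalization, method-of-moments common dispersion, Wald test on log
group means), differentiation clusters from the WT mesoderm-vs-ESC contrast,
premature-activation (C3S1) and failed-activation gene calls, association of
expression change with promoter RING1B change classes, and hypergeometric
gene-set enrichment.

Thresholds follow the global differential-expression rule
(|log2FC| > 1.5, BH-adjusted p < 0.05) unless overridden; an externally
produced DE table with the same columns can be substituted anywhere a
``DEResult`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CountMatrix

__all__ = [
    "DEResult",
    "size_factors",
    "simple_de",
    "de_result_from_table",
    "differentiation_clusters",
    "premature_activation",
    "failed_activation",
    "expression_by_binding_class",
    "geneset_enrichment",
]


@dataclass
class DEResult:
    """Per-gene differential expression between two sample groups.

    ``table`` columns: gene_id, mean_a, mean_b, log2fc, p_value, padj, status
    with status ∈ {up, down, ns}. status = up iff log2fc > lfc_cut and
    padj < alpha; down symmetric.
    """

    table: pd.DataFrame
    lfc_cut: float
    alpha: float

    def genes_with(self, status: str) -> list[str]:
        return list(self.table.loc[self.table["status"] == status, "gene_id"])

    def lookup(self, columns=("log2fc", "padj", "status")) -> pd.DataFrame:
        return self.table.set_index("gene_id")[list(columns)]


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors (DESeq-style).

    Uses genes expressed in every sample for the geometric-mean reference;
    falls back to total-count ratios if none exist.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 1:
        log_ref = np.mean(np.log(counts[positive]), axis=1)
        sf = np.exp(np.median(np.log(counts[positive]) - log_ref[:, None], axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1))))
    return sf


def _common_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled across genes and groups.

    Per gene and group: alpha = (var − mean) / mean²; the common value is the
    mean over informative genes (unbiased under the NB model, unlike the
    median, whose small-replicate skew underestimates alpha), floored at a
    small positive constant.
    """
    estimates = []
    for grp in (norm_a, norm_b):
        if grp.shape[1] < 2:
            continue
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        ok = mu > 0
        estimates.append((var[ok] - mu[ok]) / mu[ok] ** 2)
    if not estimates:
        return 1e-8
    pooled = np.concatenate(estimates)
    if len(pooled) == 0:
        return 1e-8
    return float(max(1e-8, np.mean(pooled)))


def simple_de(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
    lfc_cut: float = 1.5,
    alpha: float = 0.05,
) -> DEResult:
    """Two-sided NB Wald test of group means with median-of-ratios normalization.

    log2FC = log2((meanA + pc) / (meanB + pc)) on normalized counts (a
    pseudocount shrink for lowly expressed genes). The Wald statistic uses
    the delta-method variance of the log mean under an NB(mu, alpha) model
    with a common method-of-moments dispersion, referenced against a normal
    null; p-values are BH-adjusted across genes.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    sub = counts.submatrix(list(group_a) + list(group_b)).astype(float)
    sf = size_factors(sub)
    norm = sub / sf
    norm_a, norm_b = norm[:, : len(group_a)], norm[:, len(group_a):]
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    mu_a, mu_b = norm_a.mean(axis=1), norm_b.mean(axis=1)
    disp = _common_dispersion(norm_a, norm_b)

    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    # var(log mean) ≈ (1/(n·mu) + alpha/n) under NB(mu, alpha)
    mu_a_pc, mu_b_pc = mu_a + pseudocount, mu_b + pseudocount
    se2 = (1.0 / (n_a * mu_a_pc) + disp / n_a) + (1.0 / (n_b * mu_b_pc) + disp / n_b)
    z = (np.log(mu_a_pc) - np.log(mu_b_pc)) / np.sqrt(se2)
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p_values, method="fdr_bh")[1]

    status = np.full(len(log2fc), "ns", dtype=object)
    status[(log2fc > lfc_cut) & (padj < alpha)] = "up"
    status[(log2fc < -lfc_cut) & (padj < alpha)] = "down"
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2fc": log2fc,
            "p_value": p_values,
            "padj": padj,
            "status": status,
        }
    )
    return DEResult(table, lfc_cut, alpha)


def de_result_from_table(table: pd.DataFrame, lfc_cut: float = 1.5,
                         alpha: float = 0.05) -> DEResult:
    """Wrap an externally produced DE table (gene_id, log2fc, padj [, ...]).

    Recomputes status from the thresholds so external tables obey the same
    classification rule.
    """
    table = table.copy()
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    status = np.full(len(table), "ns", dtype=object)
    status[(table["log2fc"] > lfc_cut) & (table["padj"] < alpha)] = "up"
    status[(table["log2fc"] < -lfc_cut) & (table["padj"] < alpha)] = "down"
    table["status"] = status
    return DEResult(table, lfc_cut, alpha)


def differentiation_clusters(de_wt_mes_vs_esc: DEResult) -> pd.DataFrame:
    """Assign differentiation clusters from the WT MES-vs-ESC fold change.

    Cluster1: log2FC > 3 (activated during differentiation);
    Cluster2: log2FC < −3 (silenced); Cluster3: −0.5 < log2FC < 0.5 (stable);
    all other genes: none. Classes are disjoint by construction.
    """
    t = de_wt_mes_vs_esc.table
    lfc = t["log2fc"].to_numpy()
    cluster = np.full(len(t), "none", dtype=object)
    cluster[lfc > 3] = "Cluster1"
    cluster[lfc < -3] = "Cluster2"
    cluster[(lfc > -0.5) & (lfc < 0.5)] = "Cluster3"
    return pd.DataFrame({"gene_id": t["gene_id"], "wt_log2fc": lfc, "cluster": cluster})


def premature_activation(
    cluster_table: pd.DataFrame,
    de_ko_mes_vs_ko_esc: DEResult,
    act_cut: float = 1.5,
    alpha: float = 0.05,
) -> list[str]:
    """C3S1: differentiation-stable (Cluster3) genes activated in KO mesoderm.

    A Cluster3 gene is prematurely activated iff its KO MES-vs-ESC contrast
    is up at (act_cut, alpha).
    """
    cluster3 = set(cluster_table.loc[cluster_table["cluster"] == "Cluster3", "gene_id"])
    ko = de_ko_mes_vs_ko_esc.lookup()
    out = []
    for gene in cluster3:
        if gene not in ko.index:
            continue
        row = ko.loc[gene]
        if row["log2fc"] > act_cut and row["padj"] < alpha:
            out.append(gene)
    return sorted(out)


def failed_activation(
    cluster_table: pd.DataFrame,
    de_ko_vs_wt_in_mes: DEResult,
    fail_cut: float = -1.5,
    alpha: float = 0.05,
) -> list[str]:
    """Cluster1 genes whose mesoderm activation is significantly blunted in KO.

    A Cluster1 gene fails activation iff its KO-vs-WT MES contrast shows
    log2FC < fail_cut with padj < alpha.
    """
    cluster1 = set(cluster_table.loc[cluster_table["cluster"] == "Cluster1", "gene_id"])
    ko = de_ko_vs_wt_in_mes.lookup()
    out = []
    for gene in cluster1:
        if gene not in ko.index:
            continue
        row = ko.loc[gene]
        if row["log2fc"] < fail_cut and row["padj"] < alpha:
            out.append(gene)
    return sorted(out)


def expression_by_binding_class(
    de_ko_vs_wt: DEResult,
    lost_genes: list[str],
    unchanged_genes: list[str],
) -> dict:
    """Compare expression log2FC between RING1B-lost and RING1B-unchanged genes.

    Two-sided Wilcoxon rank-sum test of the KO-vs-WT log2FC distributions;
    effect = median(lost) − median(unchanged). Both groups must be non-empty
    after intersecting with the DE table.
    """
    lookup = de_ko_vs_wt.lookup(("log2fc",))
    lost = lookup.loc[lookup.index.intersection(lost_genes), "log2fc"].to_numpy()
    unchanged = lookup.loc[lookup.index.intersection(unchanged_genes), "log2fc"].to_numpy()
    if len(lost) == 0 or len(unchanged) == 0:
        raise ValueError("empty group after mapping genes to the DE table")
    res = stats.mannwhitneyu(lost, unchanged, alternative="two-sided")
    return {
        "n_lost": int(len(lost)),
        "n_unchanged": int(len(unchanged)),
        "median_lost": float(np.median(lost)),
        "median_unchanged": float(np.median(unchanged)),
        "median_difference": float(np.median(lost) - np.median(unchanged)),
        "p_value": float(res.pvalue),
    }


def geneset_enrichment(
    query_genes: list[str],
    universe: list[str],
    gmt_sets: dict[str, list[str]],
    min_set: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list against GMT sets.

    Each set is intersected with the universe; sets smaller than ``min_set``
    after intersection are skipped. Fold enrichment is the observed/expected
    overlap ratio. BH adjustment is across tested sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes) & universe_set
    if not set(query_genes) <= universe_set:
        outside = len(set(query_genes) - universe_set)
        raise ValueError(f"{outside} query genes are outside the universe")
    m_total = len(universe_set)
    rows = []
    for name, members in gmt_sets.items():
        in_universe = set(members) & universe_set
        k_set = len(in_universe)
        if k_set < min_set:
            continue
        overlap = len(query & in_universe)
        expected = len(query) * k_set / m_total
        p = float(stats.hypergeom.sf(overlap - 1, m_total, k_set, len(query)))
        rows.append(
            {
                "set": name,
                "set_size": k_set,
                "overlap": overlap,
                "expected": expected,
                "fold_enrichment": overlap / expected if expected > 0 else np.nan,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
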