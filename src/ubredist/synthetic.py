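"""Synthetic genomes, coverage tracks, peak sets and count matrices.

The generator plants the occupancy-redistribution structure the downstream
analyses are designed to detect, so every stage is testable without any
download:

* promoter-enriched H2AK119ub1 (gamma-distributed promoter levels) over a
  pervasive low non-promoter signal laid out in four ascending quartile
  levels;
* RING1B binding whose per-region probability increases with the
  H2AK119ub1 quartile (the binding-frequency structure);
* a knockout condition with H2AK119ub1 gain at a fraction of non-promoter
  regions (RING1B follows, modelling increased sampling) and coordinated
  H2AK119ub1/RING1B loss at a fraction of bound promoters;
* negative-binomial expression counts with planted differentiation classes
  (activated, silenced, stable), a prematurely activated stable subcluster
  and a failed-activation subcluster.

Observed coverage is simulated directly as Poisson noise on the expected
per-bp level in fixed steps (default 100 bp); read-level simulation is out
of scope. All outputs are pure functions of (config, seed); one master seed
fans out to per-component substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_io import CountMatrix, CoverageTrack, Genome, Interval, Peak, TSSRecord

__all__ = [
    "ExpressionConfig",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_tracks",
    "simulate_peak_calls",
    "simulate_expression",
    "analytic_total_signal",
]

CONDITIONS = ("WT", "KO")
MARKS = ("H2AK119ub1", "RING1B")


@dataclass
class ExpressionConfig:
    """Planted expression-class structure for the differentiation contrast."""

    n_per_class: int = 200
    n_background: int = 2000  # stable genes; keeps size-factor estimation honest
    n_replicates: int = 3
    base_mean: float = 100.0
    low_mean: float = 50.0
    dispersion: float = 0.02
    lfc_cluster1: float = 4.0  # WT MES vs ESC; must exceed the >3 cluster rule
    lfc_cluster2: float = -4.0
    lfc_intermediate: float = 1.5  # lands in the unassigned (0.5, 3) band
    lfc_c3s1: float = 2.5  # KO MES vs KO ESC for the premature subcluster
    lfc_failed: float = -2.0  # KO MES vs WT MES for the failed-activation subset
    derepression_log2fc: float = 0.5  # KO vs WT for genes with lost promoters


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 400
    promoter_halfwidth: int = 2_000
    promoter_signal_mean: float = 20.0
    promoter_signal_shape: float = 2.0
    n_nonpromoter: int = 2_000
    nonpromoter_length: int = 4_000
    nonpromoter_quartile_means: tuple = (2.0, 5.0, 12.0, 30.0)
    ring1b_freq_by_quartile: tuple = (0.05, 0.15, 0.30, 0.60)
    ring1b_promoter_freq: float = 0.9
    ring1b_promoter_level: float = 60.0
    ring1b_nonpromoter_level: float = 6.0
    background: float = 0.2
    step: int = 100
    noise: bool = True  # False → expected coverage emitted exactly
    tss_clearance: int = 3_000  # min distance of any region edge from a TSS
    ko_nonpromoter_gain_fraction: float = 0.2
    ko_gain_log2fc: float = 2.0
    ko_promoter_loss_fraction: float = 0.3
    ko_loss_log2fc: float = -2.0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 1

    def __post_init__(self):
        if isinstance(self.expression, dict):
            self.expression = ExpressionConfig(**self.expression)
        means = self.nonpromoter_quartile_means
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError("quartile means must be strictly increasing")
        for p in (*self.ring1b_freq_by_quartile, self.ring1b_promoter_freq,
                  self.ko_nonpromoter_gain_fraction, self.ko_promoter_loss_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.expression.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class SimTruth:
    """Ground-truth manifest: one row per planted region and per gene."""

    regions: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def promoters(self) -> pd.DataFrame:
        return self.regions[self.regions["kind"] == "promoter"]

    def nonpromoters(self) -> pd.DataFrame:
        return self.regions[self.regions["kind"] == "nonpromoter"]


def _rng(seed: int, component: int) -> np.random.Generator:
    """Per-component substream of the master seed (fixed spawn keys)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


def _layout(config: SimConfig) -> list[tuple[int, int, str]]:
    """Deterministic slot layout: (chrom index, slot center, 'gene'|'region').

    Gene and region slots are interleaved proportionally along equal-width
    slots so every region edge keeps ``tss_clearance`` distance from every
    TSS and TSS are at least 2 × promoter_halfwidth apart.
    """
    n_total = config.n_genes + config.n_nonpromoter
    if n_total == 0:
        return []
    total_length = config.n_chroms * config.chrom_length
    unit = total_length // n_total
    jitter = 500
    need = max(
        2 * config.promoter_halfwidth + 2 * jitter,
        config.nonpromoter_length + 2 * (config.tss_clearance + jitter),
        2 * (config.promoter_halfwidth + config.tss_clearance + jitter),
    )
    if unit < need:
        raise ValueError(
            f"genome too small: slot width {unit} bp < required {need} bp for "
            f"{config.n_genes} genes and {config.n_nonpromoter} regions"
        )
    per_chrom = config.chrom_length // unit
    slots = []
    for ci in range(config.n_chroms):
        for j in range(per_chrom):
            if len(slots) == n_total:
                break
            slots.append((ci, j * unit + unit // 2))
    if len(slots) < n_total:
        raise ValueError("genome too small to place all genes and regions")
    # proportional interleaving of gene vs region slots
    out = []
    for i, (ci, center) in enumerate(slots):
        is_gene = (
            (i + 1) * config.n_genes // n_total > i * config.n_genes // n_total
        )
        out.append((ci, center, "gene" if is_gene else "region"))
    return out


def simulate_genome(config: SimConfig, seed: int | None = None) -> tuple[Genome, list[TSSRecord]]:
    """Generate the genome and TSS annotation for a config (deterministic per seed)."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 0)
    genome = Genome(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )
    records = []
    gene_slots = [(ci, center) for ci, center, kind in _layout(config) if kind == "gene"]
    for gi, (ci, center) in enumerate(gene_slots):
        tss = int(center + rng.integers(-500, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(TSSRecord(f"gene_{gi:05d}", genome.chrom_names[ci], tss, strand))
    return genome, records


def _add_region(expected: np.ndarray, start: int, end: int, level: float, step: int):
    """Add ``level`` per-bp over [start, end) with fractional step edges."""
    first, last = start // step, (end - 1) // step
    if first == last:
        expected[first] += level * (end - start) / step
        return
    expected[first] += level * ((first + 1) * step - start) / step
    expected[first + 1 : last] += level
    expected[last] += level * (end - last * step) / step


def simulate_tracks(
    config: SimConfig,
    genome: Genome,
    tss: list[TSSRecord],
    seed: int | None = None,
) -> tuple[dict, SimTruth]:
    """Simulate {(condition, mark): CoverageTrack} plus the truth manifest.

    Expected H2AK119ub1 coverage = uniform background + a gamma promoter
    level inside each promoter domain + the assigned quartile level inside
    each non-promoter region. Expected RING1B coverage is nonzero only where
    the truth marks binding. The KO condition multiplies the H2AK119ub1
    region contribution by 2**ko_gain_log2fc at the gained non-promoter
    subset (with RING1B following at the gained level) and both marks'
    contributions by 2**ko_loss_log2fc at the lost promoter subset.
    Observed step coverage is Poisson(expected) unless ``config.noise`` is
    off.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    step = config.step
    gain_mult = 2.0 ** config.ko_gain_log2fc
    loss_mult = 2.0 ** config.ko_loss_log2fc

    # --- region bookkeeping -------------------------------------------------
    region_slots = [(ci, c) for ci, c, kind in _layout(config) if kind == "region"]
    n_np = len(region_slots)
    rows = []
    # promoters, one per gene
    n_prom = len(tss)
    prom_levels = (
        rng.gamma(config.promoter_signal_shape,
                  config.promoter_signal_mean / config.promoter_signal_shape,
                  size=n_prom)
        if n_prom else np.array([])
    )
    prom_bound = rng.random(n_prom) < config.ring1b_promoter_freq
    n_loss = int(round(config.ko_promoter_loss_fraction * n_prom))
    bound_idx = np.nonzero(prom_bound)[0]
    if n_loss > len(bound_idx):
        raise ValueError(
            f"cannot lose {n_loss} promoters: only {len(bound_idx)} are RING1B-bound"
        )
    loss_idx = set(rng.choice(bound_idx, size=n_loss, replace=False).tolist()) if n_loss else set()
    for gi, rec in enumerate(tss):
        rows.append(
            {
                "region_id": f"prom_{rec.gene_id}",
                "kind": "promoter",
                "chrom": rec.chrom,
                "start": rec.tss - config.promoter_halfwidth,
                "end": rec.tss + config.promoter_halfwidth,
                "gene_id": rec.gene_id,
                "quartile": -1,
                "h2a_level": float(prom_levels[gi]),
                "ring1b_wt": bool(prom_bound[gi]),
                "ring1b_ko": bool(prom_bound[gi] and gi not in loss_idx),
                "ko_gain": False,
                "ko_loss": gi in loss_idx,
            }
        )
    # non-promoter regions: equal-sized quartiles, shuffled placement
    quartile = np.repeat(np.arange(4), int(np.ceil(n_np / 4)))[:n_np]
    rng.shuffle(quartile)
    np_bound = rng.random(n_np) < np.asarray(config.ring1b_freq_by_quartile)[quartile]
    n_gain = int(round(config.ko_nonpromoter_gain_fraction * n_np))
    gain_idx = set(rng.choice(n_np, size=n_gain, replace=False).tolist()) if n_gain else set()
    half = config.nonpromoter_length // 2
    for ri, (ci, center) in enumerate(region_slots):
        jitter = int(rng.integers(-500, 501))
        start = center - half + jitter
        rows.append(
            {
                "region_id": f"np_{ri:05d}",
                "kind": "nonpromoter",
                "chrom": genome.chrom_names[ci],
                "start": start,
                "end": start + config.nonpromoter_length,
                "gene_id": "",
                "quartile": int(quartile[ri]),
                "h2a_level": float(config.nonpromoter_quartile_means[quartile[ri]]),
                "ring1b_wt": bool(np_bound[ri]),
                "ring1b_ko": bool(np_bound[ri] or ri in gain_idx),
                "ko_gain": ri in gain_idx,
                "ko_loss": False,
            }
        )
    truth = SimTruth(pd.DataFrame(rows))

    # --- expected coverage per step ----------------------------------------
    tracks = {}
    for condition in CONDITIONS:
        for mark in MARKS:
            runs = {}
            for ci, chrom in enumerate(genome.chrom_names):
                length = genome.chrom_lengths[ci]
                n_steps = (length + step - 1) // step
                expected = np.zeros(n_steps)
                if mark == "H2AK119ub1":
                    expected += config.background
                sub = truth.regions[truth.regions["chrom"] == chrom]
                for row in sub.itertuples():
                    if mark == "H2AK119ub1":
                        level = row.h2a_level
                        # KO scaling applies to the whole expected coverage
                        # inside the region (background included), so the
                        # planted KO/WT ratio is exact
                        if condition == "KO" and row.ko_gain:
                            level = level * gain_mult + config.background * (gain_mult - 1)
                        if condition == "KO" and row.ko_loss:
                            level = level * loss_mult + config.background * (loss_mult - 1)
                    else:  # RING1B
                        bound = row.ring1b_wt if condition == "WT" else row.ring1b_ko
                        if not bound:
                            continue
                        if row.kind == "promoter":
                            level = config.ring1b_promoter_level
                            if condition == "KO" and row.ko_loss:
                                level *= loss_mult
                        else:
                            level = config.ring1b_nonpromoter_level
                            if condition == "KO" and row.ko_gain:
                                level *= gain_mult
                    _add_region(expected, row.start, row.end, level, step)
                observed = rng.poisson(expected).astype(float) if config.noise else expected
                starts = np.arange(n_steps, dtype=np.int64) * step
                ends = np.minimum(starts + step, length)
                keep = observed > 0
                runs[chrom] = (starts[keep], ends[keep], observed[keep])
            tracks[(condition, mark)] = CoverageTrack(genome, runs)
    return tracks, truth


def simulate_peak_calls(truth: SimTruth) -> dict:
    """Emit one peak per planted signal region (summit = region midpoint).

    H2AK119ub1 peak sets contain every planted region in both conditions
    (gained regions carry low WT signal, so they are called in both); the KO
    RING1B set excludes lost promoters and includes gained non-promoter
    sites; the WT RING1B set is the WT-bound regions.
    """
    def peak_of(row):
        iv = Interval(row.chrom, int(row.start), int(row.end))
        return Peak(iv, name=row.region_id, score=float(row.h2a_level),
                    summit_offset=(iv.end - iv.start) // 2, source_format="narrowPeak")

    out = {
        ("WT", "H2AK119ub1"): [],
        ("KO", "H2AK119ub1"): [],
        ("WT", "RING1B"): [],
        ("KO", "RING1B"): [],
    }
    for row in truth.regions.itertuples():
        p = peak_of(row)
        out[("WT", "H2AK119ub1")].append(p)
        out[("KO", "H2AK119ub1")].append(p)
        if row.ring1b_wt:
            out[("WT", "RING1B")].append(p)
        if row.ring1b_ko:
            out[("KO", "RING1B")].append(p)
    return out


def simulate_expression(
    config: SimConfig,
    seed: int | None = None,
    derepressed_genes: list[str] | None = None,
    stable_genes: list[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB-distributed counts with planted differentiation classes.

    Classes (n_per_class genes each): cluster1 (activated in mesoderm,
    WT log2FC = lfc_cluster1), cluster2 (silenced), cluster3_stable,
    c3s1 (stable in WT, activated in KO mesoderm only, low baseline),
    failed_activation (cluster1-like but blunted in KO mesoderm) and
    intermediate (fold change inside the unassigned band). Optional
    ``derepressed_genes``/``stable_genes`` add genome-linked genes with a
    KO-condition derepression effect / no effect, coupling promoter-loss
    truth to expression. Returns the count matrix and the per-gene truth
    table (class, planted WT log2FC).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 2)
    ex = config.expression
    base, low = ex.base_mean, ex.low_mean

    def mean_for(klass, condition, stage):
        if klass == "cluster1":
            return base * 2.0 ** ex.lfc_cluster1 if stage == "MES" else base
        if klass == "cluster2":
            return base * 2.0 ** ex.lfc_cluster2 if stage == "MES" else base
        if klass == "cluster3_stable":
            return base
        if klass == "c3s1":
            if condition == "KO" and stage == "MES":
                return low * 2.0 ** ex.lfc_c3s1
            return low
        if klass == "failed_activation":
            if stage != "MES":
                return base
            mes = base * 2.0 ** ex.lfc_cluster1
            return mes * 2.0 ** ex.lfc_failed if condition == "KO" else mes
        if klass == "intermediate":
            return base * 2.0 ** ex.lfc_intermediate if stage == "MES" else base
        if klass == "derepressed":
            return base * 2.0 ** ex.derepression_log2fc if condition == "KO" else base
        if klass in ("stable", "background"):
            return base
        raise ValueError(klass)

    gene_rows = []
    for klass in ("cluster1", "cluster2", "cluster3_stable", "c3s1",
                  "failed_activation", "intermediate"):
        for i in range(ex.n_per_class):
            gene_rows.append((f"{klass}_{i:04d}", klass))
    for i in range(ex.n_background):
        gene_rows.append((f"background_{i:04d}", "background"))
    for g in derepressed_genes or []:
        gene_rows.append((g, "derepressed"))
    for g in stable_genes or []:
        gene_rows.append((g, "stable"))

    sample_ids, design_rows = [], []
    for condition in CONDITIONS:
        for stage in ("ESC", "MES"):
            for rep in range(1, ex.n_replicates + 1):
                sid = f"{condition}_{stage}_r{rep}"
                sample_ids.append(sid)
                design_rows.append({"sample": sid, "condition": condition,
                                    "stage": stage, "replicate": rep})
    design = pd.DataFrame(design_rows).set_index("sample")

    counts = np.empty((len(gene_rows), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        condition, stage = design.loc[sid, "condition"], design.loc[sid, "stage"]
        mus = np.array([mean_for(klass, condition, stage) for _, klass in gene_rows])
        if ex.dispersion == 0:
            counts[:, j] = np.rint(mus).astype(np.int64)
        else:
            n_param = 1.0 / ex.dispersion
            counts[:, j] = rng.negative_binomial(n_param, n_param / (n_param + mus))

    wt_lfc = {
        "cluster1": ex.lfc_cluster1, "cluster2": ex.lfc_cluster2,
        "cluster3_stable": 0.0, "c3s1": 0.0, "failed_activation": ex.lfc_cluster1,
        "intermediate": ex.lfc_intermediate, "derepressed": 0.0, "stable": 0.0,
        "background": 0.0,
    }
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g for g, _ in gene_rows],
            "class": [k for _, k in gene_rows],
            "planted_wt_log2fc": [wt_lfc[k] for _, k in gene_rows],
        }
    )
    matrix = CountMatrix([g for g, _ in gene_rows], sample_ids, counts, design)
    return matrix, gene_truth


def analytic_total_signal(config: SimConfig, genome: Genome, truth: SimTruth,
                          condition: str, mark: str) -> float:
    """Closed-form Σ expected coverage · bp for one track (mass accounting)."""
    total = 0.0
    if mark == "H2AK119ub1":
        total += config.background * genome.total_length
    gain_mult = 2.0 ** config.ko_gain_log2fc
    loss_mult = 2.0 ** config.ko_loss_log2fc
    for row in truth.regions.itertuples():
        length = row.end - row.start
        if mark == "H2AK119ub1":
            level = row.h2a_level
            if condition == "KO" and row.ko_gain:
                level = level * gain_mult + config.background * (gain_mult - 1)
            if condition == "KO" and row.ko_loss:
                level = level * loss_mult + config.background * (loss_mult - 1)
        else:
            bound = row.ring1b_wt if condition == "WT" else row.ring1b_ko
            if not bound:
                continue
            if row.kind == "promoter":
                level = config.ring1b_promoter_level
                if condition == "KO" and row.ko_loss:
                    level *= loss_mult
            else:
                level = config.ring1b_nonpromoter_level
                if condition == "KO" and row.ko_gain:
                    level *= gain_mult
        total += level * length
    return total
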