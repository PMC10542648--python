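"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate (optional) → normalize → bins → annotate →
clusters/frequency → M-value analysis → bin-change classification →
expression analysis in dependency order, writing every result table plus a
manifest (input hashes, parameters, seed, tool version). Identical config
and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    binding_frequency,
    classify_bin_regions,
    classify_region,
    labels_to_frame,
    overlap_partition,
)
from .expression import (
    differentiation_clusters,
    expression_by_binding_class,
    failed_activation,
    premature_activation,
    simple_de,
)
from .genome_io import (
    read_bedgraph,
    read_chrom_sizes,
    read_counts,
    read_peaks,
    read_tss,
    write_bedgraph,
    write_chrom_sizes,
    write_peaks,
    write_table,
    write_tss,
)
from .redistribution import (
    bin_change_classify,
    cluster_signal_test,
    frequency_vs_level_report,
    ma_normalize,
    promoter_change_classes,
    quantile_clusters,
)
from .signals import binned_average, log2_signal, make_bins, peak_intensity, rpgc_normalize
from .synthetic import (
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_peak_calls,
    simulate_tracks,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

TRACK_KEYS = [("WT", "H2AK119ub1"), ("KO", "H2AK119ub1"), ("WT", "RING1B"), ("KO", "RING1B")]


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run.

    When ``simulate`` is true, inputs are generated from ``sim`` into
    ``outdir/inputs`` and then read back through the standard readers, so the
    file formats are exercised on every run. ``scale_factors`` is either the
    string "matched" (per-track factors that restore true relative abundance
    for depth-matched tracks, the synthetic default standing in for spike-in
    calibration) or a mapping like {"WT_H2AK119ub1": 1.0, ...}.
    """

    outdir: str = "results/run"
    seed: int = 1
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # input paths, required when simulate is false
    chrom_sizes: str | None = None
    tss: str | None = None
    tracks: dict = field(default_factory=dict)  # "COND_MARK" -> bedGraph path
    peaks: dict = field(default_factory=dict)  # "COND_MARK" -> narrowPeak path
    counts: str | None = None
    design: str | None = None
    blacklist: str | None = None
    # parameters
    bin_size: int = 2000
    step: int = 100
    promoter_radius: int = 2500
    nonpromoter_min: int = 3000
    pseudocount: float = 0.01
    delta: float = 0.5
    k: int = 4
    effective_genome_size: int | None = None
    scale_factors: object = "matched"
    alpha: float = 0.05
    lfc_cut: float = 1.5
    unchanged_band: tuple = (-0.5, 0.5)
    lost_cut: float = -1.5
    min_overlap_bp: int = 1
    min_common_peaks: int = 10

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.unchanged_band, list):
            self.unchanged_band = tuple(self.unchanged_band)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # json round-trip: tuples → lists, paths → strings (yaml-safe)
        return json.loads(json.dumps(d, default=str))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every range/path violation at once (empty list = valid)."""
    errors: list[str] = []
    if config.bin_size <= 0:
        errors.append("bin_size must be positive")
    if config.step <= 0:
        errors.append("step must be positive")
    if not (0 < config.promoter_radius <= config.nonpromoter_min):
        errors.append("need 0 < promoter_radius <= nonpromoter_min")
    if config.pseudocount <= 0:
        errors.append("pseudocount must be positive")
    if config.delta < 0:
        errors.append("delta must be non-negative")
    if config.k < 1:
        errors.append("k must be at least 1")
    if not (0 < config.alpha < 1):
        errors.append("alpha must lie in (0, 1)")
    lo, hi = config.unchanged_band
    if not (config.lost_cut < lo < hi):
        errors.append("need lost_cut < unchanged_band[0] < unchanged_band[1]")
    if not config.simulate:
        required = {"chrom_sizes": config.chrom_sizes, "tss": config.tss,
                    "counts": config.counts, "design": config.design}
        for key in [f"{c}_{m}" for c, m in TRACK_KEYS]:
            required[f"tracks.{key}"] = config.tracks.get(key)
            required[f"peaks.{key}"] = config.peaks.get(key)
        for name, path in required.items():
            if not path:
                errors.append(f"missing required input path: {name}")
            elif not Path(path).exists():
                errors.append(f"input path does not exist: {name} = {path}")
    return errors


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    return str(obj)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _simulate_inputs(config: PipelineConfig, indir: Path) -> dict:
    """Generate synthetic inputs and write them as standard-format files."""
    sim = config.sim
    genome, tss = simulate_genome(sim, config.seed)
    tracks, truth = simulate_tracks(sim, genome, tss, config.seed)
    peak_sets = simulate_peak_calls(truth)
    loss_genes = list(truth.regions.loc[truth.regions["ko_loss"], "gene_id"])
    other_genes = [r.gene_id for r in tss if r.gene_id not in set(loss_genes)]
    counts, gene_truth = simulate_expression(
        sim, config.seed, derepressed_genes=loss_genes, stable_genes=other_genes
    )

    indir.mkdir(parents=True, exist_ok=True)
    paths = {"chrom_sizes": indir / "genome.chrom.sizes", "tss": indir / "tss.bed",
             "counts": indir / "counts.tsv", "design": indir / "design.tsv",
             "truth_regions": indir / "truth_regions.tsv",
             "truth_genes": indir / "truth_genes.tsv",
             "config": indir / "config.yaml", "tracks": {}, "peaks": {}}
    write_chrom_sizes(genome, paths["chrom_sizes"])
    write_tss(tss, paths["tss"])
    for (cond, mark), track in tracks.items():
        p = indir / f"{cond}_{mark}.bedgraph"
        write_bedgraph(track, p)
        paths["tracks"][f"{cond}_{mark}"] = p
    for (cond, mark), peaks in peak_sets.items():
        p = indir / f"{cond}_{mark}.narrowPeak"
        write_peaks(peaks, p, "narrowPeak")
        paths["peaks"][f"{cond}_{mark}"] = p
    pd.DataFrame(counts.counts, index=counts.gene_ids, columns=counts.sample_ids).to_csv(
        paths["counts"], sep="\t", index_label="gene_id"
    )
    counts.design.to_csv(paths["design"], sep="\t", index_label="sample")
    truth.regions.to_csv(paths["truth_regions"], sep="\t", index=False)
    gene_truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        if config.simulate:
            paths = _simulate_inputs(config, outdir / "inputs")
            track_paths = paths["tracks"]
            peak_paths = paths["peaks"]
            chrom_sizes_path, tss_path = paths["chrom_sizes"], paths["tss"]
            counts_path, design_path = paths["counts"], paths["design"]
        else:
            track_paths = {k: Path(v) for k, v in config.tracks.items()}
            peak_paths = {k: Path(v) for k, v in config.peaks.items()}
            chrom_sizes_path, tss_path = Path(config.chrom_sizes), Path(config.tss)
            counts_path, design_path = Path(config.counts), Path(config.design)

        stage = "load"
        egs = config.effective_genome_size or 0
        genome = read_chrom_sizes(chrom_sizes_path, egs)
        tss = read_tss(tss_path, genome)
        tracks = {k: read_bedgraph(p, genome) for k, p in track_paths.items()}
        peak_sets = {k: read_peaks(p, "narrowPeak", genome) for k, p in peak_paths.items()}
        counts = read_counts(counts_path, design_path)
        if config.blacklist:
            from .signals import filter_blacklist
            black = read_peaks(config.blacklist, "bed3", genome)
            peak_sets = {k: filter_blacklist(v, black) for k, v in peak_sets.items()}

        stage = "normalize"
        egs_val = genome.effective_genome_size
        if config.scale_factors == "matched":
            sfs = {k: t.total_signal() / egs_val for k, t in tracks.items()}
        else:
            sfs = {k: float(config.scale_factors.get(k, 1.0)) for k in tracks}
        calibrated = {
            k: rpgc_normalize(t, egs_val, sfs[k]) for k, t in tracks.items()
        }

        stage = "bins"
        grid = make_bins(genome, config.bin_size)
        bin_signals = {
            k: binned_average(t, grid, label=tuple(k.split("_", 1)))
            for k, t in calibrated.items()
        }
        bin_region = classify_bin_regions(
            grid, tss, config.promoter_radius, config.nonpromoter_min
        )

        stage = "annotate"
        labels = {
            k: classify_region(v, tss, config.promoter_radius, config.nonpromoter_min)
            for k, v in peak_sets.items()
        }
        for k, labs in labels.items():
            write_table(labels_to_frame(labs), outdir / f"peaks_{k}.tsv",
                        {"promoter_radius": config.promoter_radius,
                         "nonpromoter_min": config.nonpromoter_min})

        stage = "clusters"
        wt_h2a_labels = labels["WT_H2AK119ub1"]
        np_idx = [i for i, l in enumerate(wt_h2a_labels) if l.region_class == "non_promoter"]
        np_peaks = [wt_h2a_labels[i].peak for i in np_idx]
        h2a_intensity = peak_intensity(calibrated["WT_H2AK119ub1"], np_peaks, config.step)
        assignment = quantile_clusters(h2a_intensity, np_peaks, config.k)
        peaks_by_cluster = {
            c: [np_peaks[i] for i in assignment.members(c)] for c in assignment.clusters
        }
        frequencies = binding_frequency(
            peaks_by_cluster, peak_sets["WT_RING1B"], config.min_overlap_bp
        )
        ring1b_density = peak_intensity(calibrated["WT_RING1B"], np_peaks, config.step)
        freq_table, spearman_rho = frequency_vs_level_report(
            assignment, frequencies, h2a_intensity, ring1b_density
        )
        write_table(freq_table, outdir / "cluster_frequency.tsv", {"k": config.k})
        signal_test = cluster_signal_test(
            {c: log2_signal(ring1b_density[assignment.members(c)], config.pseudocount)
             for c in assignment.clusters}
        )
        write_table(signal_test, outdir / "cluster_signal_test.tsv")

        stage = "manorm"
        ma_results = {}
        for mark in ("RING1B", "H2AK119ub1"):
            ko, wt = peak_sets[f"KO_{mark}"], peak_sets[f"WT_{mark}"]
            part = overlap_partition(ko, wt, config.min_overlap_bp)
            all_peaks = part.shared_a + part.unique_a + part.unique_b
            side = np.array(
                ["common"] * len(part.shared_a)
                + ["unique_a"] * len(part.unique_a)
                + ["unique_b"] * len(part.unique_b)
            )
            d_ko = peak_intensity(calibrated[f"KO_{mark}"], all_peaks, config.step)
            d_wt = peak_intensity(calibrated[f"WT_{mark}"], all_peaks, config.step)
            lengths = np.array([len(p.interval) for p in all_peaks], dtype=float)
            ma = ma_normalize(
                d_ko, d_wt, side, config.pseudocount, lengths, config.step,
                config.min_common_peaks,
            )
            peak_labels = classify_region(
                all_peaks, tss, config.promoter_radius, config.nonpromoter_min
            )
            ma.table.insert(0, "name", [p.name for p in all_peaks])
            ma.table["region_class"] = [l.region_class for l in peak_labels]
            ma.table["nearest_gene"] = [l.nearest_gene for l in peak_labels]
            write_table(ma.table, outdir / f"manorm_{mark}.tsv",
                        {"slope": f"{ma.slope:.6g}", "intercept": f"{ma.intercept:.6g}"})
            ma_results[mark] = ma

        ring1b_ma = ma_results["RING1B"].table
        prom_mask = ring1b_ma["region_class"] == "promoter"
        prom_classes = promoter_change_classes(
            ring1b_ma.loc[prom_mask, "m_rescaled"].to_numpy(),
            config.unchanged_band, config.lost_cut,
        )
        prom_classes.insert(0, "name", ring1b_ma.loc[prom_mask, "name"].to_numpy())
        prom_classes["nearest_gene"] = ring1b_ma.loc[prom_mask, "nearest_gene"].to_numpy()
        write_table(prom_classes, outdir / "promoter_change_classes.tsv",
                    {"unchanged_band": config.unchanged_band, "lost_cut": config.lost_cut})

        stage = "binchange"
        change = bin_change_classify(
            bin_signals["KO_H2AK119ub1"], bin_signals["WT_H2AK119ub1"],
            bin_signals["KO_RING1B"], bin_signals["WT_RING1B"],
            config.delta, config.pseudocount, bin_region,
        )
        write_table(change.table, outdir / "bin_change.tsv", {"delta": config.delta})
        change_props = change.proportions(by_region=True)

        stage = "expression"
        de = {}
        contrasts = {
            "WT_MES_vs_ESC": (dict(condition="WT", stage="MES"), dict(condition="WT", stage="ESC")),
            "KO_MES_vs_ESC": (dict(condition="KO", stage="MES"), dict(condition="KO", stage="ESC")),
            "KO_vs_WT_MES": (dict(condition="KO", stage="MES"), dict(condition="WT", stage="MES")),
            "KO_vs_WT_ESC": (dict(condition="KO", stage="ESC"), dict(condition="WT", stage="ESC")),
        }
        for name, (crit_a, crit_b) in contrasts.items():
            de[name] = simple_de(
                counts, counts.samples_where(**crit_a), counts.samples_where(**crit_b),
                lfc_cut=config.lfc_cut, alpha=config.alpha,
            )
            write_table(de[name].table, outdir / f"de_{name}.tsv",
                        {"lfc_cut": config.lfc_cut, "alpha": config.alpha})
        clusters = differentiation_clusters(de["WT_MES_vs_ESC"])
        write_table(clusters, outdir / "differentiation_clusters.tsv")
        c3s1 = premature_activation(clusters, de["KO_MES_vs_ESC"],
                                    config.lfc_cut, config.alpha)
        failed = failed_activation(clusters, de["KO_vs_WT_MES"],
                                   -config.lfc_cut, config.alpha)
        lost_genes = sorted(set(prom_classes.loc[prom_classes["change_class"] == "lost",
                                                 "nearest_gene"]))
        unchanged_genes = sorted(set(prom_classes.loc[prom_classes["change_class"] == "unchanged",
                                                      "nearest_gene"]) - set(lost_genes))
        binding_assoc = None
        try:
            binding_assoc = expression_by_binding_class(
                de["KO_vs_WT_ESC"], lost_genes, unchanged_genes
            )
        except ValueError as exc:
            logger.warning("binding-class association skipped: %s", exc)

        stage = "report"
        summary = {
            "n_peaks": {k: len(v) for k, v in peak_sets.items()},
            "cluster_binding_frequency": {
                c: frequencies[c]["frequency"] for c in assignment.clusters
            },
            "spearman_cluster_frequency": spearman_rho,
            "ma_fit": {m: {"slope": ma_results[m].slope, "intercept": ma_results[m].intercept}
                       for m in ma_results},
            "promoter_change_counts": prom_classes["change_class"].value_counts().to_dict(),
            "bin_change_proportions": {
                str(region): {cls: float(change_props.loc[region, cls])
                              for cls in change_props.columns}
                for region in change_props.index
            },
            "de_counts": {name: {"up": int((d.table["status"] == "up").sum()),
                                 "down": int((d.table["status"] == "down").sum())}
                          for name, d in de.items()},
            "differentiation_cluster_sizes": clusters["cluster"].value_counts().to_dict(),
            "n_c3s1": len(c3s1),
            "n_failed_activation": len(failed),
            "expression_by_binding_class": binding_assoc,
        }
        _write_json(summary, outdir / "summary.json")

        manifest = {
            "tool": "ubredist",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v for k, v in config.to_dict().items()
                if k not in ("tracks", "peaks", "sim")
            },
            "sim": config.to_dict()["sim"] if config.simulate else None,
            "inputs": {
                "chrom_sizes": _sha256(chrom_sizes_path),
                "tss": _sha256(tss_path),
                "counts": _sha256(counts_path),
                "design": _sha256(design_path),
                **{f"track_{k}": _sha256(p) for k, p in sorted(track_paths.items())},
                **{f"peaks_{k}": _sha256(p) for k, p in sorted(peak_paths.items())},
            },
        }
        _write_json(manifest, outdir / "manifest.json")
        return summary
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
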