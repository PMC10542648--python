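# Methods

This note records the models behind `ubredist`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Coordinate and signal conventions

All intervals are 0-based half-open (BED convention); 1-based annotation
inputs are converted at the reader boundary so no off-by-one can drift
through the pipeline. Coverage tracks are piecewise-constant, non-negative
signals with implicit zeros; all signal reads (bin averages, peak
intensities, anchor matrices) are exact length-weighted integrals over that
step function, which makes them invariant to how runs are split and lets the
test suite compare them to per-base brute force at 1e-9.

RPGC (1×) normalization rescales a track so its length-weighted mean over
the effective genome equals the scale factor:
`out = in × (EGS / Σ in·bp) × s`. The effective genome size is a scalar on
the `Genome` (for mouse GRCm38 the conventional value is 2,494,787,188 bp;
synthetic genomes default to their own length). The scale factor is a
config input carrying external calibration (e.g. spike-in derived); RPGC
alone equalizes means across conditions and therefore erases genuine global
differences. For the synthetic study, where conditions are depth-matched by
construction, the pipeline's `"matched"` mode sets each track's factor to
`Σ coverage·bp / EGS`, which restores true relative abundance exactly — the
role a spike-in calibration plays on real data.

**Peak intensity** is the mean of the five largest 100-bp step averages
within the peak (all steps when fewer than five), reflecting signal
extraction from fixed-bin normalized coverage tracks; per-base maxima would
be noise-dominated. A caveat that matters when interpreting fold changes:
the top-five statistic is an order statistic, so at low Poisson means it is
biased upward relative to the true level, and the bias is larger for the
weaker of two conditions. Ratios of top-five intensities therefore compress
large fold changes at low coverage (measured at roughly −0.2 to −0.3 log2
for a planted +2 log2 change at single-digit expected coverage). The M~A
rescaling removes shared systematic trends but not this per-peak
small-sample effect; the default simulation keeps promoter RING1B levels
high enough (60× background-free) that promoter-loss calls are unaffected.

## M-value differential occupancy

For each peak present in either condition, with pseudocounted densities
`dA, dB` (pseudocount 0.01): `M = log2(dA/dB)`, `A = ½·log2(dA·dB)`. A line
`M = a + b·A` is fitted on **common** peaks only and subtracted from every
peak, extrapolating the condition-wide trend (sequencing-depth scaling,
intensity-dependent bias) to condition-unique peaks.

The fit is a Huber robust regression rather than ordinary least squares.
The rescaling is meant to track the *unchanged majority* of common peaks;
with a genuinely changed minority (in the default simulation, 20 % of
non-promoter peaks gain +2 log2, and the change is correlated with A), OLS
tilts toward the changed peaks, absorbing ~40 % of the planted effect and
pushing unchanged peaks off zero. The Huber loss downweights those peaks
and restores both properties (planted affine trends removed to a median
residual < 0.01; planted gains recovered at their planted magnitude).
Degenerate inputs (no spread in A or in M) fall back to a zero-slope,
median-intercept line.

Significance is a two-sided conditional binomial test: the rescaled trend is
moved onto side B, densities are converted to step-count equivalents
(density × peak length / step, rounded), and `xA` is tested against
`xA + xB` at p = 0.5, with Benjamini–Hochberg correction across peaks. This
matches the count nature of coverage; it is a simplified stand-in for the
published M-A normalization tool's internal model, which is not specified in
enough detail to reproduce. Fewer than 10 common peaks is an error: a fitted
trend would be meaningless.

## Promoter classification and change classes

A peak is a promoter peak if its summit (narrowPeak column 10, else the
interval midpoint) lies within 2.5 kb of a TSS, and non-promoter if ≥ 3 kb
from every TSS. Summits in the open (2.5 kb, 3 kb) gap form an explicit
`ambiguous` class, excluded from promoter/non-promoter contrasts and counted
in the log — the definitions leave that band unassigned and inventing a
boundary would silently move peaks between contrasts. Signed distance is
negative upstream of the TSS on the gene's strand; equidistant ties resolve
to the upstream TSS and are logged. Bin-level region classes apply the same
rule with the bin midpoint standing in for the summit.

Promoter RING1B change classes from rescaled M (KO as side A):
unchanged M ∈ [−0.5, 0.5]; lost M < −1.5; other the rest. The classes are
disjoint and exhaustive by construction.

## Quartile clusters and binding frequency

C1–C4 are rank quartiles of non-promoter H2AK119ub1 peak intensity (low to
high), sizes differing by at most one, ties broken by genomic coordinate so
the assignment is deterministic. Binding frequency per cluster is the
fraction of its peaks overlapping ≥ 1 RING1B peak by ≥ 1 bp (the minimal
overlap criterion, exposed as a flag). Cross-cluster signal comparisons use
two-sided Wilcoxon rank-sum tests with BH correction across the reported
family. The Spearman ρ of cluster index vs frequency is reported, not
tested: with k = 4 there are only four ranks.

## Bin-change classification

On a fixed 2-kb grid, Δ = log2((KO + 0.01)/(WT + 0.01)) per mark per bin;
both_up iff both marks' Δ > 0.5, both_down iff both < −0.5, unchanged iff
both |Δ| ≤ 0.5, discordant otherwise. δ = 0.5 mirrors the promoter
"unchanged" band; δ = 0 degenerates to sign-only concordance and is exposed
in the config. Proportions are reported overall and stratified by the bin's
region class; near-zero background bins produce a large discordant fraction
by noise alone, so interpretation should focus on bins with signal (the
planted-change recovery tests do exactly that).

## Differential expression

The in-repo DE test is deliberately simple and fully specified:
median-of-ratios size factors (geometric-mean reference over genes expressed
in every sample); per-gene group means of normalized counts; a single
method-of-moments NB dispersion `α = mean over genes of (var − μ)/μ²`
pooled across groups — the mean, not the median, because the small-replicate
skew of the variance estimate biases the median low, which made the test
anticonservative (null type-I 0.10 instead of 0.05) — and a Wald statistic
on the log group means with delta-method variance `1/(n·μ) + α/n` per group
against a normal reference. log2FC uses a +1 pseudocount on normalized
means as shrinkage for lowly expressed genes. Genes are called up/down at
|log2FC| > 1.5 and BH-adjusted p < 0.05. An externally produced DE table
(gene_id, log2fc, padj) can be wrapped via `de_result_from_table`, so a
full-featured NB framework's output can be substituted; status is then
recomputed from the same thresholds.

Differentiation clusters come from the WT mesoderm-vs-ESC contrast:
Cluster 1 log2FC > 3, Cluster 2 < −3, Cluster 3 strictly inside ±0.5,
everything else unassigned. C3S1 is the subset of Cluster 3 called up
(log2FC > 1.5, padj < 0.05) in the KO MES-vs-ESC contrast; failed
activation is the subset of Cluster 1 with log2FC < −1.5 and padj < 0.05 in
the KO-vs-WT mesoderm contrast. These subcluster thresholds reuse the
global DE rule, since no separate thresholds are published; both are
config-exposed. The promoter-loss/expression association maps promoter
peaks to their nearest-TSS gene and compares KO-vs-WT log2FC distributions
of lost vs unchanged genes with a two-sided rank-sum test (effect = median
difference). Gene-set enrichment is a one-sided hypergeometric tail per set
against a user universe with BH correction — a deliberate, transparent
stand-in for ontology-aware enrichment machinery (no GO DAG handling).

## Synthetic data: what it emulates, and what it does not

The generator lays out genes and non-promoter regions on equal-width slots
(with ±500 bp jitter) so that promoter domains never overlap and every
non-promoter region edge keeps ≥ 3 kb from every TSS — labels are
unambiguous by construction. Expected H2AK119ub1 coverage is a uniform
background (0.2) plus a gamma level (mean 20, shape 2) inside each ±2 kb
promoter domain plus the assigned quartile level (2, 5, 12, 30) inside each
4-kb non-promoter region; quartiles are equal-sized and placed at random.
RING1B expected coverage is nonzero only where bound: promoters with
probability 0.9 at level 60, non-promoter regions with quartile-dependent
probability (0.05, 0.15, 0.30, 0.60) at level 6. The knockout multiplies
the whole expected coverage inside 20 % of non-promoter regions by 2² (with
RING1B following at the gained level, modelling increased sampling of
gained chromatin) and inside 30 % of bound promoters by 2⁻². Observed
coverage is Poisson(expected) per 100-bp step (`noise=False` emits the
expectation exactly, which the mass-accounting and exact-ratio tests use).
The promoter RING1B level (60) is set high relative to step noise so that a
−2 log2 loss is resolvable through the top-five intensity estimator (see
the order-statistic caveat above); 6 for non-promoter binding reflects the
weak, transient occupancy the binding-frequency analysis is designed
around.

Peak calls are emitted from the truth manifest (one peak per planted
region, summit at the midpoint): peak calling itself is out of scope, and
emitting truth regions keeps recovery tests exact. Expression counts are
NB(μ, dispersion 0.02) at 3 replicates over WT/KO × ESC/MES, with planted
classes of 200 genes each — activated (+4 log2 in mesoderm), silenced (−4),
stable, C3S1 (baseline 50, +2.5 log2 in KO mesoderm only), failed
activation (+4 in WT mesoderm, 2⁻² of that in KO mesoderm), an intermediate
class (+1.5, inside the unassigned band) — plus 2000 stable background
genes. The background majority keeps median-of-ratios size factors honest;
without it, composition bias compressed every planted fold change. Class
means and dispersion were fixed by a delta-method power check: at μ ≥ 50,
α = 0.02, n = 3, the log2FC standard error is ≈ 0.23, so stable genes stay
inside the ±0.5 Cluster-3 band with ~97 % probability and ±4 log2 effects
are detected essentially always. Genome-linked genes can be appended with a
+0.5 log2 KO derepression (for promoters that lose RING1B), coupling the
occupancy and expression sides of the simulation.

One master seed fans out to per-component substreams via fixed spawn keys,
so every output is a pure function of (config, seed) and components are
individually reproducible.

What the generator does **not** emulate: read-level artifacts (fragment
length, GC bias, mappability), peak-calling uncertainty, replicate coverage
tracks, correlated biological variability between neighbouring genes, and
composition differences between conditions beyond the planted gains/losses.
Passing recovery tests therefore demonstrates that the analysis logic is
correct and calibrated under the stated noise model, not that it is robust
to every artifact of real sequencing data.

## Pipeline and determinism

`run_pipeline` executes simulate (optional) → load → normalize → bins →
annotate → clusters/frequency → M-value → bin-change → expression →
report, writing TSV tables with parameter header comments, a summary JSON
and a manifest (input SHA-256 hashes, parameters, seed, version; no
timestamps). Synthetic inputs are written to standard formats and read back
through the ordinary readers, so the file layer is exercised on every run.
Identical config and seed give byte-identical outputs; any stage failure
aborts with the stage name. Problem sizes of the default study (2 × 20 Mb
genome, 2000 non-promoter regions, 400 genes, ~3200 expression genes) were
chosen so a full run completes in seconds while keeping binomial recovery
error well inside the tested tolerances.

## Known limitations

* The binomial M-value significance model treats step-count equivalents as
  independent counts; spatial autocorrelation within peaks makes it
  anti-conservative for long peaks. Rankings and class calls (which use M,
  not p) are unaffected.
* The common NB dispersion is a single pooled value; strongly
  mean-dependent dispersion would miscalibrate tails (shrinkage-based
  per-gene dispersion is deliberately out of scope).
* `classify_feature` uses summit position with a fixed priority; whole-peak
  overlap fractions are not implemented.
* bigWig I/O is not included; tracks are exchanged as bedGraph behind the
  same `CoverageTrack` contract.
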