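# Methods

This note documents the statistical models, defaults and numerical choices
behind `rrgkit`, and what the synthetic-data tests do and do not establish.

## The %RRG statistic

Let *D* be an upregulated DEG set for one hormone/timepoint contrast, and let
x_gc = ln(1 + 10⁴·c_gc / total_c) be log-normalized expression.

**Baseline.** For each g ∈ *D*, μ_g and σ_g are the mean and sample standard
deviation (n−1 denominator) of the *nonzero* x_gc over timepoint-matched
vehicle ERα+ cells. Zero exclusion makes the baseline a property of the
expressing-cell distribution rather than of detection dropout. Genes with
fewer than two nonzero baseline values have no estimable σ and are excluded
from the denominator (imputing them would create σ = 0 artifacts where any
nonzero value "responds"); the exclusion is logged and the denominator is
constant across cells within a run.

**Responding rule.** Gene g responds in cell c iff x_gc > μ_g + σ_g, strict.
Zeros in evaluated cells count as expression 0 (they can never respond, since
μ_g + σ_g > 0 whenever defined); the zero-exclusion clause applies to
baseline estimation only. %RRG(c) = 100 · responding / defined.

Because the threshold is one SD above the mean, a null cell drawn from the
baseline distribution triggers the rule with probability ≈ Φ(−1) ≈ 0.159 per
Gaussian-like gene; on sparse counts the realized floor is lower (zeros never
respond). This produces the stable nonzero %RRG floor shared by vehicle and
ERα− cells — an expected property, not a bug — and it is what the
Gaussian-tail acceptance check verifies on zero-free Gaussian baselines.

**Choices the source workflow leaves open.** Sample vs population SD:
sample SD (recorded in provenance). Baseline population for *all* evaluated
cells, including ERα− and vehicle cells, is vehicle ERα+ (the one population
the workflow names); an ERα−-derived baseline can be supplied by mask.
Vehicle cells' own %RRG is computed against the baseline estimated from
themselves; the self-referential bias is O(1/n_baseline) per gene and
negligible at the cell numbers used here (the null-calibration check bounds
it empirically).

**Comparison.** `compare_rrg` reports per-group medians, the median ratio,
and the two-sided Mann–Whitney U test (tie-corrected normal approximation
with continuity correction). All-tie inputs return p = 1.

**Bimodality.** Declared when (a) Hartigan's dip test rejects at α = 0.05
with a seeded bootstrap (200 uniform samples — the asymptotically least
favourable unimodal null) and (b) a 2-component Gaussian mixture beats 1
component by > 10 BIC points. Both thresholds are package defaults standing
in for visual identification of responder/non-responder subpopulations. The
dip statistic is implemented from scratch (GCM/LCM modal-interval iteration)
and validated in the test suite against an independent linear-programming
oracle that optimises directly over unimodal CDFs (mode jumps allowed) on
small samples, plus closed-form cases (dip = 1/(2n) for distinct n ≤ 3;
dip = 1/4 for two equal point masses).

## Differential expression

Per-gene two-sided Mann–Whitney U on log-normalized values, mid-rank tie
correction, continuity correction; genes constant across both groups get
p = 1. log₂FC = log₂((mean(eˣ−1)+1)/(mean(eˣ−1)+1)) across groups
(pseudocount 1 on the de-logged scale). BH step-up over all genes tested in
the contrast (no prefilter-then-adjust; no min.pct prefilter by default).
DEG gate: padj < 0.05 strict, |log₂FC| ≥ 0.25 inclusive, restricted to
positive log₂FC for the %RRG pipeline. The bulk-convention gate (0.585)
is available by argument.

Accuracy of the normal approximation: because tie-free p-values depend only
on (n_a, n_b, U), the test suite compares `wilcoxon_gene_test` against exact
permutation enumeration *exhaustively over every possible outcome* at group
sizes 5–8; the worst deviation is 0.0173. At group sizes ≤ 4 the worst-case
deviation provably exceeds 0.02 (0.0305 at 4v4, 0.088 at 2v2), so no
approximation-vs-exact bound of 0.02 can hold there; groups that small should
use an exact test, and the enumeration oracle in the tests shows how.

## Matrix operations

- Mito QC: cells with 100·mito/total > 10 removed (strict >). Mito genes come
  from a boolean `var["mito"]` column or the mouse `mt-` symbol-prefix rule;
  a rule matching nothing warns and keeps all cells, no rule at all is an
  error. Idempotent.
- Log-normalization: scale factor 10⁴, natural log (the convention the
  standard single-cell workflow implies); zero-total cells are an error
  naming the barcode; zeros map to zeros and sparsity is preserved.
- Depth matching: independent per-entry binomial thinning with retention
  p = target_mean/source_mean. This matches mean depth in expectation and is
  a deliberate dialect difference from scuttle's `downsampleMatrix`
  (per-cell without-replacement sampling); at UMI scales the difference is
  negligible, and the acceptance check realises the target within 1%.
- Gene-positive fraction: ≥ 1 UMI by default (`min_umi` configurable).

## Signature scoring and lineage projection

Module scores follow the Tirosh strategy: genes ranked by mean expression
across cells, split into `n_bins = 24` equal-count bins, `n_ctrl = 100`
control genes per signature gene drawn from the matching bin, score = mean
signature expression − mean pooled control expression per cell. Defaults are
the widely used ones; the source workflow does not state them. One deviation
from the common with-replacement convention: when a bin holds at most
`n_ctrl` genes the whole bin is used exhaustively (sampling without
replacement otherwise), which is lower-variance at identical expectation and
makes scores exactly zero when controls cover the gene universe. The RNG
protocol (single seeded generator, signatures then genes in order) is
documented and mirrored by the brute-force oracle in the tests; drawn
controls are recorded in the result.

Rescaling is min–max to [0, 1] per signature over all scored cells jointly
(not per sample); constant vectors map to 0.5 with a warning. Ternary
coordinates divide the rescaled (basal, luminal progenitor, mature luminal)
triple by its sum; all-zero triples map to the centroid. Cell-cycle phase:
G1 if both scores ≤ 0, otherwise the larger of S/G2M, ties toward S
(logged). S/G2M gene lists are supplied as input files; human→mouse ortholog
mapping is upstream and out of scope.

## Association

Spearman (mid-rank, t-approximation p) and Pearson (t, n−2 df) between a
candidate gene's log-normalized expression (zeros included) and per-cell
%RRG, default subset hormone-treated ERα+ cells. Constant inputs yield
missing values with a warning. No multiple-testing correction by default for
small candidate panels; BH columns by flag.

## Nuclear positivity

The contract starts at per-nucleus median intensities (segmentation is
upstream). Thresholds: `otsu` (default) maximises between-class variance
over all splits of the sorted sample *on the log1p intensity scale*, where
background and positive fluorescence components are approximately Gaussian —
raw-scale, histogram-binned Otsu is biased into the skewed positive
component and parks thresholds at bin edges; the returned threshold is on
the raw scale, and the test suite cross-checks against scikit-image's
implementation. `first_valley` takes the midpoint of the first smoothed
local minimum dipping below half the dominant background peak; `manual`
passes a value through (the visual-refinement escape hatch). Positivity is
strict (ties at the threshold are negative). Aggregation reports
per-organoid n, %ERα+, %PR+, %double-positive, their medians/ranges over
organoids (one point per organoid), and global P(ERα+ | PR+).

## Synthetic data

`generate_counts` emulates the targeted experimental design: cells split
evenly over a condition × timepoint grid (default vehicle/E2 × 4h/16h), an
ERα+ fraction of 0.20 by default (assigned deterministically for exact group
sizes), gamma-Poisson counts with per-gene lognormal abundance
(σ = 1.5), dispersion 0.3, lognormal mean-one size factors (σ = 0.3) at
5000 expected UMIs/cell, 10 mito genes carrying 5% of transcriptome mass,
and 200 planted hormone-responsive genes capped at 5% of baseline mass —
the cap matters: without it, hormone induction inflates treated-cell totals
enough that depth normalization visibly dilutes every other gene and
induces a spurious negative regulator–%RRG correlation.

Hormone response is per cell *and* per gene: in treated ERα+ cells each
responsive gene's NB mean is multiplied by 2^effect_log2fc with probability
a_c, the cell's activation fraction. a_c is zero for all vehicle and ERα−
cells. The responder model is either `uniform` (a ~ U(0,1)) or `bimodal`
(mixture of two jittered modes, defaults 0.1/0.7 with equal weight — the
responder/non-responder picture); activation is drawn by (monotone) quantile
transform, so rank correlations planted through the copula carry through
exactly. The effect size is a free parameter (default 2×): the underlying
biology does not pin per-gene induction magnitudes, so planted effects are
study conditions, not estimates.

The co-regulator covariate is an actual synthetic gene (`Coreg1`, 0.5% of
transcriptome mass, mean-one lognormal biological variation σ = 0.6). The
activation fraction is coupled by Gaussian copula to the *realized*
log-normalized Coreg1 expression (Blom normal scores of the generated
counts), i.e. to the same observable the association stage later measures —
coupling to a hidden latent would attenuate the planted correlation by the
gene's counting noise. Responsive entries of treated ERα+ cells are then
redrawn at the boosted mean; at effect 0 the redraw reproduces the baseline
law exactly, preserving treated/vehicle exchangeability (verified by test).
Draws come from a single seeded `numpy` Generator in a fixed vectorised
order; identical configs give bitwise-identical matrices.

`generate_signature_cells` plants disjoint 100-gene lineage modules
over-expressed by a stated factor at 10⁴ UMIs/cell, dispersion 0.2, with the
mean vector renormalised so depth is archetype-independent. Module size and
depth were chosen so that min–max rescaled scores separate cleanly — curated
lineage signatures are of comparable size — and with factor ≥ 4 each
archetype's cells recover their own ternary vertex.

`generate_intensity_table` draws each channel from a two-component lognormal
mixture (background median 100, positive = 5× by default, σ = 0.25);
PR+ nuclei are a nested subset of ERα+ nuclei under the default co-positivity
rule (independent as an option). Truth labels are included. Note the
recovery checks use a 20×-separated mixture when they need literally zero
misclassification (exact 100% conditional co-expression); at the 5× default
the recovered conditional is ~99.8%.

## Problem sizes and calibration conditions

The acceptance measurements run at desk scale, chosen as the smallest sizes
at which the properties are comfortably identified: tail-probability check
at 5000 baseline × 1000 evaluated cells × 200 genes; null calibration over
50 seeds at 400 cells × 300 genes (with effect 0 the DEG gate is empty by
design, so the %RRG stage runs on the planted panel, an arbitrary gene set
under the null, while the DE stage's empirical FDR is measured); effect
detection over 20 seeds at 200 cells/group × 1000 genes with 100 planted
genes at 2× effect; bimodality over 20 seeds at 500 treated ERα+ cells
(modes 0.1/0.7 vs a single-mode control at 0.4); co-regulator recovery at
ρ ∈ {0, 0.25, 0.5, 0.75} over 20 seeds with 1000 treated ERα+ cells,
150 responsive genes, 2× effect, depth 10⁴ — conditions set by a power
analysis of the rank-correlation attenuation chain (counts → expression
ranks → activation → %RRG), which predicts ≈ 0.9 retention; positivity
recovery over 10 seeds × 10⁴ nuclei.

## What passing does and does not show

The generator embodies the same distributional assumptions the analysis
makes. Green tests therefore demonstrate internal correctness (formulas,
thresholds, edge cases, calibration under the stated model) and faithful
recovery of planted structure — not robustness to ambient RNA, doublets,
batch effects, misassigned clusters, or non-NB noise in real organoid data.
Quantities that depend on the original study's deposited data (specific
correlation values, organoid positivity medians, peak counts) are not
reproducible from synthetic data and are not targets here; the pipeline
reproduces the *procedures* that computed them.
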