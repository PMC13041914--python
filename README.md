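# rrgkit

Single-cell analysis of hormone-response heterogeneity built around the
per-cell **ratio of responding genes (%RRG)** statistic, for mammary-organoid
style scRNA-seq experiments in which only a subpopulation of cells (ERα+
hormone sensors) is expected to respond to estrogen (E2) or progesterone (P4)
treatment.

Receptor transcript abundance is a poor single-cell predictor of hormone
response; %RRG instead quantifies, for every cell, *how much of the hormone
program it engages*, enabling questions like "do co-regulator levels (Ncoa1,
Ncor1, Ncor2) track response magnitude?" and "is the response bimodal
(responders vs non-responders)?".

## The statistic

For a hormone/timepoint contrast:

1. **DEG selection.** Per-gene two-sided Wilcoxon rank-sum tests compare
   hormone-treated with vehicle ERα+ cells on log-normalized expression
   x = ln(1 + 10⁴·c/total); BH-adjusted p-values and log₂ fold changes (Seurat
   convention, pseudocount 1 on the de-logged scale) gate genes into the
   upregulated DEG set *D*: padj < 0.05 (strict) and log₂FC ≥ 0.25.
2. **Zero-excluded baseline.** For each g ∈ *D*, μ_g and σ_g (sample SD) are
   estimated from the **nonzero** log-normalized values in timepoint-matched
   vehicle ERα+ cells; genes with fewer than two nonzero baseline values are
   dropped from the denominator.
3. **Responding rule.** Gene g responds in cell c iff x_gc > μ_g + σ_g
   (strict), and

   %RRG(c) = 100 · #{g ∈ D defined : x_gc > μ_g + σ_g} / #{g ∈ D defined}.

4. **Comparison.** Treated and vehicle %RRG distributions are compared with
   two-sided Wilcoxon rank-sum tests; ERα− cells serve as an internal
   negative control. Bimodality is assessed jointly by Hartigan's dip test
   (seeded uniform bootstrap) and a 1-vs-2 component Gaussian-mixture BIC
   comparison.

Companion modules cover the surrounding workflow: mito-percentage QC,
log-normalization, binomial depth downsampling, gene-positive fractions,
Tirosh-style signature module scores with 0–1 rescaling and ternary lineage
projection (basal / luminal progenitor / mature luminal), cell-cycle phase
calls, regulator–%RRG correlation (Spearman + Pearson), and nuclear
marker-positivity quantification from per-nucleus intensity tables
(histogram-derived thresholds, per-organoid aggregation, ERα/PR
co-positivity). A fully seeded synthetic-data generator with planted ground
truth (`rrgkit.synthdata`) makes every stage testable without any download.

## Worked example

```python
from rrgkit import synthdata, pipeline

cfg = synthdata.SimConfig(
    n_cells=2000, n_genes=1000, n_responsive=100, frac_erpos=0.2,
    conditions=("vehicle", "E2"), timepoints=("4h",), effect_log2fc=1.5,
    responder_model="bimodal", seed=7,
)
adata, truth = synthdata.generate_counts(cfg)
res = pipeline.hormone_response_analysis(adata, hormone="E2", timepoint="4h")

print("up-DEGs selected:", len(res.deg_selection.genes))
c = res.comparison
print(f"median %RRG: treated ERa+ {c.median_a:.1f}  vehicle ERa+ {c.median_b:.1f}  "
      f"ratio {c.median_ratio:.2f}  Wilcoxon p {c.pvalue:.3g}")
print(res.rrg_cells.groupby("group")["pct_rrg"].median().round(2))
```

prints

```
up-DEGs selected: 54
median %RRG: treated ERa+ 23.1  vehicle ERa+ 11.1  ratio 2.08  Wilcoxon p 3.61e-40
group
treated_ERneg    11.11
treated_ERpos    23.15
vehicle_ERneg    11.11
vehicle_ERpos    11.11
```

Read: the Wilcoxon/BH gate recovered 54 upregulated DEGs; treated ERα+ cells
engage a median 23% of that panel versus the ~11% false-positive floor that
every control group shares (the +1 SD rule fires by chance in a stable
fraction of genes), a 2.1-fold induction with overwhelming rank-sum evidence.
The ERα− groups are flat across treatment, as an internal negative control
should be.

The same stages are scriptable from a shell: `rrgkit simulate counts`,
`rrgkit qc`, `rrgkit normalize`, `rrgkit downsample`, `rrgkit score`,
`rrgkit de`, `rrgkit rrg`, `rrgkit associate`, `rrgkit positivity`
(see `rrgkit --help`). Matrices travel as 10x-convention Matrix Market
triplets, gene sets as plain text or GMT, intensity tables as CSV.

## Limitations

The synthetic generator shares the analysis' distributional assumptions
(gamma-Poisson counts, multiplicative effects); passing recovery checks shows
the pipeline is self-consistent and correctly implemented, not that real
organoid data meet those assumptions. Ambient RNA, doublets, batch effects
and cluster-assignment error are out of scope, as are upstream read
quantification, graph clustering/UMAP, and image segmentation. See
`docs/methods.md` for models, defaults and numerical choices.
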