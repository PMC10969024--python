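# evproteo

A tested, reusable pipeline for label-free proteomic biomarker discovery
in cerebrospinal fluid (CSF) and its extracellular-vesicle (EV)
fractions, aimed at the kind of study where waste CSF from
extraventricular drainage is profiled by mass spectrometry across three
clinical groups — pilocytic astrocytoma cases (PA), congenital
hydrocephalus controls (CH) and medulloblastoma tumor controls (MB) —
and three biochemical fractions: unprocessed total CSF (Tot), small EVs
(SEV, <200 nm) and large EVs (LEV, >200 nm).

It is written for computational proteomics practitioners who receive a
protein-group intensity table (e.g. MaxQuant LFQ output) plus a sample
sheet and need the complete downstream statistical workflow with
reproducible, seeded results.

## What it computes

Given a protein × sample log2-intensity matrix **X** with missing
entries and a 3 group × 3 fraction factorial design:

- **Preprocessing** — 70 %-presence filtering (in ≥ 1 design cell),
  left-censored imputation with draws from
  N(μ_s − 1.8 σ_s, (0.3 σ_s)²) per sample, quantile normalization, and
  per-protein Z-scores for heatmaps.
- **Unsupervised structure** — Spearman-correlation outlier screen,
  classical (Torgerson) MDS on the 1 − ρ distance with k-means on the
  embedding, agglomerative hierarchical clustering.
- **Differential abundance** — one-way ANOVA across design cells; Welch
  t-tests for PA-vs-CH, PA-vs-MB and PA-vs-nonPA per fraction and
  pooled; Benjamini–Hochberg q-values; volcano significance by the
  hyperbolic cutoff y ≥ |c/(x − x₀)| with q ≤ α; Venn/panel
  intersection logic across comparisons.
- **PLS-DA + VIP** — NIPALS PLS2 against one-hot class labels; variable
  importance in projection
  VIP_j = √(P · Σ_a SSY_a w²_aj / Σ_a SSY_a), mean(VIP²) = 1; k-means
  on the score plane with a Rand index against PA/non-PA.
- **Enrichment** — rank-based 2D annotation enrichment
  (s = 2(r̄_in − r̄_out)/n ∈ [−1, 1] per dimension, Mann–Whitney p, BH,
  permutation band around the x = y diagonal) and Fisher-exact kinase
  substrate enrichment from GMT gene sets.
- **Assay validation** — relative titers (RU/mL) from a serial two-fold
  dilution ELISA standard curve, Kruskal–Wallis group tests, empirical
  ROC with DeLong CI/p, Youden-index cutoff, positive likelihood ratio
  LR⁺ = sens/(1 − spec), qualitative AUC bands, and a-priori two-sample
  sample-size planning with exact noncentral-t power.
- **Synthetic data** — a generator producing LFQ-like matrices with a
  known ground truth (fraction structure, spiked PA markers, logistic
  intensity-dependent missingness) for end-to-end recovery testing.

## Worked example

Simulate a default dataset (1000 proteins, 72 samples, two spiked
markers: `CPXM2_like` +3 log2 in PA, `AQP4_like` −3) and run the whole
discovery workflow:

```sh
evproteo simulate --seed 0 --out demo/sim
evproteo run-all --intensities demo/sim/intensities.tsv \
    --sheet demo/sim/sample_sheet.tsv --seed 0 --out demo/results
```

The VIP ranking (`demo/results/vip.tsv`) puts both spiked markers far
ahead of the background:

```
                 VIP
CPXM2_like  8.462610
AQP4_like   8.371269
P00847      3.184215
```

and the per-fraction differential table
(`differential_PA-vs-CH_Tot.tsv`) recovers them with the right signs:

```
              log2fc             p             q  significant
CPXM2_like  2.792992  2.578235e-11  2.560188e-08         True
AQP4_like  -2.774207  4.408544e-09  2.188842e-06         True
```

(log2fc is oriented so positive means higher in PA; `significant`
combines BH q ≤ 0.05 with the hyperbolic volcano cutoff.)  The MDS
embedding + k-means (`mds_embedding.tsv`) groups samples by fraction,
not by clinical group, and k-means on the PLS-DA scores separates PA
from non-PA samples exactly — the two qualitative behaviours the
analysis is designed around.

The same steps are available as library calls
(`evproteo.synthetic.generate_dataset`, `evproteo.preprocess.*`,
`evproteo.differential.*`, `evproteo.multivariate.*`, ...) and as the
other CLI subcommands (`preprocess`, `differential`, `plsda`, `enrich`,
`validate-assay`).

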