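# lingbrain

Tools for linking automatically derived speech features to clinical symptoms
and brain imaging measures in clinical-high-risk (CHR) psychosis research —
and, more generally, for any two-block brain/behavior covariation analysis
built on sparse canonical correlation.

Speech disturbance is a core feature of the psychosis spectrum, and interview
transcripts are cheap to collect. This package implements a complete,
reproducible pipeline from raw transcripts and imaging-derived tables to
permutation-tested multivariate covariation patterns:

1. **Linguistic features** (`lingbrain.lingfeat`): per-subject amount of
   speech (min/max/mean/sd words per sentence), semantic coherence (cosine of
   consecutive sentence vectors in a latent semantic analysis space), and
   Penn Treebank part-of-speech tag frequencies; cohort-level filtering of
   degenerate features (modal share > 50%).
2. **Brain features** (`lingbrain.brainfeat`): resting-state network
   cohesiveness (mean within-network Fisher-z correlation) and hub-centric
   network integration over a 6-network atlas (11 measures per subject), plus
   validated ingestion of 68 cortical-thickness + 20 subcortical-volume
   morphometry tables.
3. **Site harmonization** (`lingbrain.harmonize`): parametric empirical-Bayes
   ComBat, cross-checked against the Bioconductor reference implementation.
4. **Sparse CCA** (`lingbrain.scca`): penalized-matrix-decomposition modes
   with unit-norm, L1-bounded weights; grid-searched sparsity; max-statistic
   permutation inference (the null statistic is the maximal correlation over
   the full grid re-search per permutation, so the p-value is corrected for
   sparsity selection); rank-1 deflation for further modes.
5. **Synthetic studies** (`lingbrain.synthgen`): transcripts from POS-templated
   grammars, feature blocks with planted sparse canonical modes, one-factor
   network time series, morphometry tables, and case–control metadata — all
   pure functions of a seed, so every stage is testable without clinical data.

## The model

For z-scored blocks X (n × p₁) and Y (n × p₂), a canonical mode is

    maximize  u′ X′Y v   subject to  ‖u‖₂ = ‖v‖₂ = 1, ‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂

solved by alternating soft-thresholded power iterations on X′Y with exact
L1-ball projections and two-start initialization. The reported canonical
correlation is r = corr(Xu, Yv). The sparsity budgets (c₁, c₂) maximize r over
a 10 × 10 grid on [1, √p] per side, and significance uses

    p = #(permuted max-over-grid r  >  observed r) / n_perm

with rows of Y permuted (default n_perm = 10,000). Weight magnitudes indicate
each feature's contribution to the mode.

## Worked example

Generate a synthetic two-site study (46 CHR + 22 healthy subjects) and run the
three standard analyses — language vs clinical items within CHR, and
language (+ diagnosis, handedness) vs connectivity and vs morphometry in the
whole sample:

```bash
lingbrain simulate --out study --seed 7 --n-sentences 25 --timepoints 120
lingbrain run --config study_config.yaml
```

with `study_config.yaml`:

```yaml
transcripts: study/transcripts
metadata: study/metadata.tsv
timeseries: study/timeseries
morphometry: study/morphometry.tsv
atlas: study/atlas.json
out_dir: results_study
semantic_k: 25
analyses:
  - {name: language_clinical, block_y: clinical,
     subset: {diagnosis: CHR}, n_perm: 500, seed: 1}
  - {name: language_connectivity, block_y: connectivity,
     indicators: [diagnosis, handedness], n_perm: 500, seed: 1}
  - {name: language_morphometry, block_y: morphometry,
     indicators: [diagnosis, handedness], n_perm: 500, seed: 1}
```

prints (about 3 minutes on one core)

```
language_clinical: r = 0.726, p = 0.302
language_connectivity: r = 0.599, p = 0.174
language_morphometry: r = 0.851, p = 0.058
```

Each line is one analysis' first canonical mode: `r` is the in-sample
correlation between the weighted language score and the weighted clinical or
imaging score, and `p` is its max-statistic permutation p-value. On this null
synthetic study (nothing links language to the other blocks) the in-sample
correlations are large — with 20 retained language features, 19–88 opposing features
and grid-searched sparsity, overfitting is expected — but none of the modes
survives the selection-corrected permutation test, which is exactly the
protection the test provides. `results_study/` then contains per-analysis JSON
(weights, grid trace, per-mode p-values), sorted weight tables
(`*_weights_x.tsv`, `*_weights_y.tsv`), the ComBat model dumps, and a run
manifest with the config hash and every subject exclusion; reruns are
byte-identical. Inspect the most heavily weighted features with

```bash
lingbrain report --result results_study/language_connectivity.json --side y
```

```
+0.8022	coh_ECN
+0.5903	int_LAN_ECN
+0.0781	int_LAN_SAL
-0.0443	coh_LAN
...
```

The same stages are available as library calls (`run_study`,
`run_scca_analysis`, `language_features`, `connectivity_vector`,
`combat_fit`/`combat_transform`, ...) and as individual CLI subcommands
(`features-language`, `features-brain`, `harmonize`, `scca`, `report`). A
pooled-imaging analysis is a single TSV holding the concatenated imaging
blocks passed to `lingbrain scca`.

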