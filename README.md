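# lpscourse

Analysis toolkit for dense promoter/enhancer expression time courses of the
kind produced by CAGE profiling of LPS-stimulated monocyte-derived
macrophages (MDM): a 3-donor, 26-timepoint course of promoter-level TPM,
plus companion condition-group matrices, motif-count matrices and GWAS
summary statistics. It is aimed at computational biologists who want the
whole analysis pattern — denoising through disease-variant enrichment — as
a reusable, tested library rather than a collection of one-off scripts.

The pipeline stages, each usable on its own:

* **Denoising & filtering** — replicate-pool outlier replacement (a value
  deviating > 3 SD from the mean of its pool of 8 temporal/donor
  neighbours is replaced by the pool mean), donor averaging, TPM
  normalization, and the expression filter (max ≥ 10 TPM in some
  timepoint, coefficient of variation > 0.5).
* **Coexpression clustering** — Pearson graph at r ≥ 0.9 and an in-repo
  Markov Cluster (MCL) implementation (inflation 1.6 for promoter
  networks; sample-to-sample networks at r ≥ 0.95, inflation 2.2),
  clusters size-ordered with per-cluster mean profiles.
* **Candidate selection** — the a-priori expression-pattern criteria
  (down-regulated on monocyte→MDM differentiation, specifically induced by
  a monocyte stimulus, ≥ 5-fold monocyte↔MDM change) and the
  SNP-proximal subset (TSS within 2 kb of a variant with p < 1e-6).
* **MARA** — motif activity response analysis: ridge decomposition
  E' ≈ N·A of double-centred log2 expression over a feature × motif count
  matrix, with activity standard errors, Z-scores and a per-motif
  significance ranking.
* **Enhancer timing** — peak/onset estimation on the time grid and
  enhancer-promoter lead-lag tables (lead = promoter peak − enhancer peak)
  for pairs within ±500 kb.
* **GWAS enrichment** — observed:expected ratios of significant variants
  in 1,000 bins spanning ±1 Mb around a TSS set, and a resampling "burden
  of significance" test (±100 kb windows, best-variant scores, null sets
  drawn from a promoter universe).
* **Synthetic data** — a generator that emulates the whole study with
  planted ground truth (archetype labels, spike masks, candidate sets,
  motif activities, enhancer leads, enriched TSS), which the tests use as
  their oracle.

## Worked example

Simulate a small study and run every stage:

```bash
cat > demo.yaml <<EOF
n_features: 500
n_enhancers: 100
n_variants: 5000
n_motifs: 8
EOF
lpscourse run-all --config demo.yaml --seed 11 --outdir demo_out
```

which prints `pipeline complete; outputs in demo_out` and writes, among
others, `filtered_profiles.tsv`, `clusters.tsv`, `candidates.tsv`,
`motif_zscores.tsv`, `lead_lag.tsv`, `bin_profile.tsv` and a
`manifest.json` whose summary block for this config and seed reads:

```
n_outliers_replaced 250
n_clusters 5
n_candidates 50
lead_lag {'frac_positive_lead': 0.854, 'median_lead_minutes': 120.0, 'n_pairs': 301}
burden {'statistic': 21.26, 'empirical_p': 0.015}
```

Reading those numbers: the smoother touched 250 of 39,000 tensor cells
(the ~0.6% background of a 3-SD rule plus the planted spikes); MCL found
the 5 non-flat response archetypes the generator planted; 50 of 500
features (the planted 10%) pass both candidate criteria; the median
enhancer lead equals the planted 120 minutes, with the positive-lead
fraction diluted below 1.0 because distance pairing within ±500 kb also
produces spurious enhancer-promoter pairs; and the planted 10-fold variant
enrichment near candidate TSS is detected at p = 0.015 against 199
resampled promoter sets.

The same stages are available as library calls (`gen_timecourse`,
`replace_outliers`, `mcl_cluster`, `select_candidates`,
`MotifActivityModel`, `lead_lag`, `enrichment_profile`, `burden_pvalue`,
...) and as individual subcommands (`simulate`, `preprocess`, `cluster`,
`select`, `mara`, `timing`, `enrich`). The estimator classes
(`OutlierSmoother`, `ExpressionFilter`, `MarkovClustering`,
`MotifActivityModel`) follow scikit-learn conventions (`fit`/`transform`,
`get_params`/`set_params`, fitted attributes with trailing underscores).

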