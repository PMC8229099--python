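# methylclass

Analysis pipeline for DNA-methylation beta matrices (CpG sites x samples,
values in [0, 1], `NaN` for missing calls):

* **simulate** — synthetic cohorts with a bimodal background beta
  distribution, planted per-subtype hyper/hypo-methylation signatures,
  an optional planted methylation group that scales outcome hazards,
  missingness and a matched detection p-value matrix
  (`methylclass.simulate`);
* **preprocess** — detection-p masking (calls with p >= 0.05 become
  missing), probe filtering (blacklist, autosomal list, >10% missingness)
  and classical-MDS outlier flagging (`methylclass.preprocess`);
* **feature selection** — union over cross-validation folds of PCA-loading
  selection (top 20 CpGs by absolute loading on each of the first 15
  components) and the low-variance/high-correlation filter (variance >=
  0.1, pairwise |r| <= 0.7) (`methylclass.features`);
* **classification** — nested cross-validated (outer 5, inner 3)
  one-vs-rest model bank of nine families with train-split-only median
  imputation, Wilcoxon model comparison, label-permutation validation
  and prediction of samples without a subtype label
  (`methylclass.classify`);
* **differential methylation** — one-vs-rest Mann-Whitney per subtype
  with Benjamini-Hochberg correction within subtype and subtype-unique
  CpG extraction (`methylclass.differential`);
* **heterogeneity** — intra-subtype hierarchical clustering and
  cluster-vs-covariate association via Fisher's exact and Welch t tests
  (`methylclass.heterogeneity`);
* **survival** — relapse-associated CpG ranking, high/low methylation
  grouping, Kaplan-Meier curves, log-rank tests and a Newton-Raphson
  Cox proportional-hazards fit with Breslow tie handling
  (`methylclass.survival`).

## CLI

Every stage is a subcommand of `methylclass`; `run-all` chains them from
a flat key-value configuration file:

```sh
methylclass simulate --n-cpgs 5000 --seed 1 --out-prefix cohort
methylclass preprocess --beta cohort_beta.tsv \
    --detection-p cohort_detection_p.tsv --out filtered.tsv
methylclass select-features --beta filtered.tsv --out features.tsv
methylclass train --beta filtered.tsv --sheet cohort_sheet.tsv \
    --features features.tsv --out model_selection.tsv
methylclass run-all --config pipeline.conf --out-dir run --seed 1
```

Config keys mirror `methylclass.config.PipelineConfig` (one
`key = value` per line); every flag overrides the file.  All artifacts
are tab-separated text; a `manifest.json` in the run directory records
parameters, per-stage seeds and file checksums so runs are
bit-reproducible.

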