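# normdev

Normative deviation mapping of regional cortical thickness, packaged as a
tested, reusable pipeline:

1. **Synthetic cohorts** (`normdev.simulate`) — multi-site reference,
   control and patient ROI tables (148 Destrieux-style regions by default)
   with per-site offset/scale effects, sparse injected extreme negative
   deviations plus a diffuse shift in patients, and longitudinal PANSS-like
   item tables generated from a mixed model whose negative-symptom
   trajectory depends on baseline deviations. Injected ground truth is
   emitted for downstream recovery tests.
2. **Normative model** (`normdev.normative`) — per-region Gaussian model of
   thickness on an age spline plus sex, with site offsets as shrunken
   random effects and site noise scales under a log-normal hyperprior.
   Unseen sites are adapted from a held-out fraction of their controls
   (closed-form shrinkage offset, MAP scale); adaptation subjects are then
   discarded and test subjects converted to per-region z-scores.
3. **Deviation maps** (`normdev.deviations`) — extreme masks at |z| >= 2.6
   (inclusive), per-region overlap percentages and overall proportions.
4. **Group statistics** (`normdev.stats`) — region-wise Mann-Whitney U
   (exact permutation distribution when min(n) <= 8, tie-corrected normal
   approximation otherwise), Benjamini-Hochberg step-up FDR, rank-biserial
   effect sizes, and a 2x2 chi-square for the site-exclusion sensitivity
   analysis.
5. **Clinical scores** (`normdev.clinical`) — PANSS domain sums, Andreasen
   remission status (P1, P2, P3, N1, N4, N6, G5, G9 all <= 3) and the
   summed remission score.
6. **Outcome models** (`normdev.lme`) — Gaussian linear mixed models
   (random intercept + week slope, REML via statsmodels) and a
   Laplace-approximate logistic mixed model, run per region with BH
   correction across regional z-coefficient p-values.
7. **Pipeline + CLI** (`normdev.pipeline`, `normdev.cli`) — end-to-end
   driver with a JSON run manifest, deterministic given a single seed.

## Test

```bash
python -m pytest -q tests/
```

## CLI

```bash
normdev run-all --out out/             # built-in synthetic demo config
normdev run-all --config pipeline.yaml --seed 1 --out out/
normdev simulate --config cohort.yaml --seed 1 --out data/
normdev fit-reference --reference data/reference.csv --out model.json
normdev adapt --model model.json --controls data/clinical.csv --min-controls 10 --out adapted/
normdev deviate --model model.json --test test.csv --adaptation adapted/site_adaptation.csv --out dev/
normdev overlap --zscores dev/zscores.csv --covariates dev/zscore_covariates.csv --threshold 2.6 --out maps/
normdev compare --zscores dev/zscores.csv --covariates dev/zscore_covariates.csv --alpha 0.05 --out tests.csv
normdev predict-outcomes --zscores dev/zscores.csv --covariates dev/zscore_covariates.csv \
    --clinical panss.csv --outcome negative --out outcome.csv
```

Pipeline YAML keys mirror `normdev.pipeline.PipelineConfig` (seed,
adaptation_fraction, threshold, alpha, min_controls,
strict_site_exclusion, input paths or inline simulation configs, ...).

## Data formats

- ROI tables: UTF-8 CSV, long layout with columns
  `subject_id, site_id, sex, age, group, role, region_id, thickness`
  (wide layout with one column per region is also readable).
- Deviation matrices: wide z-score CSV (one row per subject) plus a
  covariate sidecar CSV.
- Normative model: JSON with an explicit schema version.
- Clinical tables: CSV with `subject_id, week, P1..P7, N1..N7, G1..G16`.
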