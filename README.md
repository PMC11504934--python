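# exwaskit

An end-to-end, seed-deterministic pipeline for exposome-wide association
screening (ExWAS) of participant-level cohort data with family-within-site
nesting, and for building and validating coefficient-weighted cumulative
risk scores in a held-out subsample.

The pipeline stages are:

1. **Synthetic cohort generation** (`exwaskit.synthetic_cohort`) — seeded
   cohorts with families nested in sites, demographic covariates, a
   mixed-type exposure battery (binary/ordinal/continuous) with planted
   collinear pairs (|r| > 0.9) and rare (<1%) items, signed true exposure
   effects on a continuous T-score outcome, a calibrated rare binary
   outcome, subgroup shifts in exposure burden, MCAR/MAR missingness on the
   exposures only, and a family-integral site-stratified train/test split.
   Ground truth (true coefficients, null set, variance components) is
   emitted alongside for recovery testing.
2. **Exposure curation** (`exwaskit.exposure_prep`) — hour/minute item
   combination, low-endorsement (<1%) filtering, upper-tail Q3 + k·IQR
   outlier removal, iterative random-forest imputation (missForest-style
   stopping rule, train and test imputed separately), and greedy
   mean-absolute-correlation collinearity pruning decided on the training
   subsample only.
3. **Mixed models** (`exwaskit.mixed_models`) — REML linear mixed models
   with random intercepts for family nested within site, fitted by an exact
   closed-form profile of the two variance ratios (fast enough for
   thousands of screening fits; agrees with `statsmodels.MixedLM` to ~1e-3
   and verified against a dense grid-search oracle), Nakagawa-style
   marginal R², ICC, and plain logistic regression with Wald odds-ratio
   intervals.
4. **Screening** (`exwaskit.exwas_engine`) — one mixed model per exposure
   with screening covariates (age, sex, Black race, White race, Hispanic
   ethnicity), Benjamini–Hochberg FDR over the tested family, and
   risk/protective classification.
5. **Risk scoring** (`exwaskit.risk_scoring`) — per-participant weighted
   sum of FDR-significant exposures with their signed training-sample
   coefficients, z-scored within the held-out subsample.
6. **Validation** (`exwaskit.validation`) — nested M1–M4 mixed models
   (demographics → +non-social screentime → +non-digital adversity →
   +risk score) on one common row set with marginal R² increments,
   rare-outcome logistic models, top-decile outcome binarization, and
   E-value confounding sensitivity.
7. **Disparities** (`exwaskit.disparities`) — Kruskal–Wallis,
   Dunn–Holm pairwise tests, Mann–Whitney with the rank-biserial effect
   size, and score-by-group interaction models with stratified simple
   slopes.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria (identities
recomputable from reported values, FDR calibration on an all-null
generator, coefficient/score recovery, nested-model ΔR² behaviour, oracle
equivalences, and pipeline-hygiene checks). The simulation-heavy tests run
in a few minutes on one CPU.

## CLI

The `exwas` entry point chains the full pipeline over plain-text artifacts:

```bash
exwas simulate --seed 7 --out cohort.csv                 # + cohort.csv.truth.json
exwas prep     --in cohort.csv --out prepped.csv --report prep.json
exwas screen   --train prepped.csv --out exwas.tsv --log screen.json
exwas score    --test prepped.csv --exwas exwas.tsv --out scores.csv
exwas validate --test prepped.csv --scores scores.csv --out report.json
exwas disparities --test prepped.csv --scores scores.csv \
    --groups race3,sex,sgm --out disp.tsv
```

`exwas prep` accepts `--no-outlier-removal` and `--listwise` to reproduce
the outlier-retention and list-wise-deletion sensitivity variants.
Generator settings can be overridden with `--config cfg.json` (keys of
`SimConfig`).

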