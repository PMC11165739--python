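# hatkit

Construction and validation of a continuous 0–10 latent-health score for
aging cohorts, exercised end to end on a calibrated synthetic
multi-cohort generator.

The score integrates five health indicators — gait speed (m/s), global
cognition (MMSE, 0–30), chronic-disease count (0–60), instrumental ADL
limitations (0–8) and personal ADL limitations (0–6) — via a nominal
response model (NRm): candidate cut-off sets per indicator are
enumerated, an NRm is fitted per candidate by marginal maximum
likelihood (EM + Gauss–Hermite quadrature), the most informative
candidate is selected with 10-split internal-consistency checking,
per-category weights are derived by regressing EAP latent scores on
item-category dummies, and raw scores are min–max rescaled to 0–10 over
the theoretical profile space.  Validation covers AUC from unadjusted
logistic regressions (DeLong CIs), Cox regression with Harrell's C,
age/sex-stratified runs, two-stage fixed-effect individual-participant
meta-analysis with leave-cohort-out reruns, and score-percentile
geriatric charts (logistic quantile regression on a four-knot restricted
cubic spline of age) overlaid with outcome-risk contours.

Because the underlying cohort data are access-restricted, the package
ships a first-class synthetic generator (`hatkit.synthetic_cohorts`)
that reproduces the published baseline marginals of four cohorts
(n = 3363/1402/2931/766, complete-case inclusion 3096/1228/2390/588,
pooled 7302), including two realistic defects: one cohort with
systematically missing gait speed (imputed by predictive mean matching)
and one cohort where planned hospital admissions cannot be separated
from unplanned ones.

## Layout

```
src/hatkit/
  synthetic_cohorts.py  calibrated multi-cohort generator
  cohort_io.py          CSV schema, unit standardization, harmonization
  imputation.py         predictive mean matching (type-1 PMM)
  nrm_engine.py         Bock nominal response model: EM, TCC/TIF, EAP
  hat_builder.py        cut-off grid search, weights, 0-10 scoring
  validation.py         AUC/DeLong, Harrell's C, strata, reliability
  ipd_meta.py           fixed-effect inverse-variance pooling
  charts.py             percentile charts + risk surfaces
  pipeline_cli.py       orchestration and the `hat` CLI
```

## CLI

```bash
hat run-all --seed 1 --out scratch/run1      # full pipeline, default config
hat simulate --seed 1 --out scratch/sim      # cohort CSVs only
hat build --seed 1 --out scratch/build       # HAT construction only
hat run-all --config my_run.yaml             # YAML-configured run
```

`run-all` produces cohort CSVs, the harmonization report, imputation
provenance, HAT model JSONs (per cohort and harmonized), tidy validation
and meta-analysis CSVs (full, minus-imputed-cohort, minus-development-
cohort), chart exports, and a `manifest.json` with sha256 checksums of
every artifact.  Runs are bit-reproducible given the same config and
seed.  Exit codes: 0 ok, 2 config error, 3 stage failure.

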