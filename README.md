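# semcohort

Maximum-likelihood covariance-structure modelling (confirmatory factor
analysis, second-order factors, structural paths) implemented from
scratch, together with a seeded synthetic biomarker-cohort generator and
the staged analysis pipeline that runs on it.

The package covers:

* **`semcohort.sem`** — an ML covariance-structure engine: declarative
  model text (`factor`, `second_order`, `observed_exogenous`, `path`),
  model-implied covariance `Sigma = Lam (I-B)^-1 Psi (I-B)^-T Lam' + Th`,
  the discrepancy `F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`
  minimized with an analytic gradient, multi-start L-BFGS-B and a Newton
  polish; chi-square / RMSEA / CFI fit statistics, standard errors from
  the inverse observed information, fully standardized solutions,
  composite (construct) reliabilities, indirect effects as products of
  chain coefficients, and regression-method (Thomson) factor scores.
* **`semcohort.cohort`** — a fully explicit, seeded generator producing
  cohorts with a three-factor + second-order latent structure driven by
  the standardized selenium/age quotient, calibrated marker-age
  correlations, two measurement occasions with factor-specific
  test-retest autocorrelation and arm shifts, and a binary 5-year
  cardiovascular-death endpoint (per-arm rates in RCT mode, selenium-
  quartile rates in observational mode).
* **`semcohort.pipeline`** — the analysis stages in order: log
  preprocessing, age partial-correlation check, selenium/age quotient,
  three-factor CFA, the full second-order structural model, per-arm
  48-month factor-score change tests, the cardiovascular-age regression
  and the selenium-quartile mortality chi-square test.
* **`semcohort.io` / `semcohort.cli`** — RFC-4180 cohort CSV reading and
  writing, YAML configuration with strict key checking, run manifests,
  and the `semcohort` command-line tool.

## CLI

```sh
# simulate a cohort (baseline + 48 months + mortality) to CSV
semcohort simulate --seed 1 --out cohort.csv

# fit the measurement model or the full structural model
semcohort fit-cfa --data cohort.csv --out cfa.json
semcohort fit-sem --data cohort.csv --out sem.json

# run every stage and write report.json / summary.txt / manifest.json
semcohort pipeline --seed 1 --out-dir run/

# selenium-quartile mortality chi-square
semcohort mortality-test --data cohort.csv
```

A YAML config mirroring `GeneratorConfig` can be passed with
`--config`; unknown keys are rejected and omitted keys keep their
documented defaults.

## Model text format

```
factor inflammation: tnfr1 tnfr2 opg opn
factor myocardium: ntprobnp fix_error=0
second_order infl_ox: inflammation oxidative_stress
observed_exogenous sel_age
path sel_age -> infl_ox
path infl_ox -> fibrosis
```

One statement per line, `#` comments, whitespace-delimited. Marker
identification (first loading fixed to 1) is the default;
`unit-latent-variance` is also supported, and both yield identical
standardized solutions.
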