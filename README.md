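# claimscohort

Estimating the burden of **untreated insomnia disorder** from longitudinal
medical-claims tables: cohort construction, daytime-impairment and clinical
endpoints, inverse-probability-of-treatment-weighted (IPTW) effect
estimates, and bootstrap inference — plus a synthetic claims generator with
analytic ground truth so the entire chain can be validated without access to
any proprietary claims source.

## Who this is for

Epidemiologists and biostatisticians running new-user-style cohort analyses
on administrative claims: patients with a diagnosed but untreated condition
(here insomnia disorder, ICD-10 F51.0x / G47.0x / G47.8 / G47.9) compared
with controls free of the diagnosis and of treatment, on outcomes proxied by
ICD-10 codes (fatigue R53.82/R53.83, somnolence R40.0, disorientation R41.0,
dizziness R42, plus cardiometabolic, psychiatric, respiratory and
neurological conditions).

## The design and the statistics

**Patient-treatments.** The analysis unit is one cohort-membership episode
with its own index date and observation window:

* *untreated insomnia* — index at the first eligible insomnia diagnosis; the
  window rolls forward while further insomnia codes arrive less than 183
  days apart, and closes at the earlier of that gap expiring, the first
  insomnia treatment (benzodiazepines, z-drugs, trazodone, DORAs,
  ramelteon, tetra-/tricyclics), or the end of enrollment;
* *non-insomnia* — index at the first day with a full 1-year look-back of
  enrollment, provided no insomnia/circadian diagnosis or insomnia
  treatment has occurred; the first such event thereafter closes the
  window. The same patient can legitimately appear in both cohorts.

Eligibility everywhere: age ≥ 18, a full 1-year look-back inside enrollment,
no pregnancy / palliative-care / malignancy code in the look-back. Cleaning:
same-day duplicate claims are collapsed; patient-treatments with more than
50 look-back diagnoses of disorientation or sleep paralysis are dropped as
outliers.

**Endpoints.** For each endpoint, unit *i* contributes a response
`(y_i, t_i)`:

* **rate** — `y` = event count in the window, `t` = window years;
* **annualized occurrence** — `y` = 1{≥ 1 event}, `t` = window years;
* **prevalence** (rare chronic conditions) — windows are first truncated to
  a common reference duration (default 131 days) in expectation — each
  cohort keeps the first `131 / mean-duration` fraction of every window —
  then `y` = 1{≥ 1 event in the truncated window}, normalized back to one
  year.

**Weighting and inference.** Cohort membership is modelled by logistic
regression on baseline covariates (standardized age, sex, and twenty
look-back comorbidity flags); ATE weights are `w = 1/p` (exposure) and
`1/(1−p)` (control). Bias-corrected cohort means are

```
rate / annualized:   mu_c = sum_i(w_i y_i) / sum_i(w_i t_i)
prevalence:          mu_c = sum_i(w_i y_i) / sum_i(w_i)
```

scaled to 100 patient-years, and `ATE = mu_untreated − mu_control`.
Inference is a two-sided bootstrap test (patient-treatments resampled with
replacement, propensity model refit in every resample; default 512
resamples) with percentile 95% CIs and an add-one p-value
`p = 2·min(#{b≤0}+1, #{b≥0}+1)/(n+1)`; covariate balance requires the 95th
percentile of bootstrapped weighted standardized differences to fall below
0.15; Benjamini–Hochberg FDR correction is applied across the full endpoint
× subgroup grid (full population, young-healthy < 40, females 40–55,
elderly ≥ 65).

## Worked example

```python
import dataclasses
from claimscohort import RunConfig, run_study

cfg = RunConfig(seed=7, n_boot=199)
cfg.simulation = dataclasses.replace(cfg.simulation, n_patients=2000)
report = run_study(cfg, "out")
```

This generates 2,000 synthetic patients (claims written under `out/claims/`
with their analytic ground truth), builds both cohorts, and runs the
weighted analysis. With this seed the attrition log reads

```
patients_total 2000 | untreated_insomnia 376 | non_insomnia 1998
outlier_removed 1   | eligible_total 2374
```

(2,374 = 376 + 1,998: patients diagnosed after a clean first year appear in
both cohorts). The full-population daytime-impairment rows of
`report.results`:

```
      endpoint  mu_untreated  mu_control   ate  ci_low  ci_high  p_raw  p_adjusted
disorientation          0.37        0.84 -0.47   -0.97     0.17   0.22        0.52
     dizziness         14.87       11.41  3.46   -1.54     9.71   0.26        0.52
       fatigue         44.98       20.13 24.85   14.65    35.87   0.01        0.05
    somnolence          7.50        1.11  6.39    2.64    10.65   0.01        0.05
```

All values are events per 100 patient-years. The generator planted a
fatigue rate ratio of 2.5 over a base rate of 18.7/100 PY, i.e. a true
additive effect of 31.1/100 PY after covariate rate effects — inside the
bootstrap CI (14.65, 35.87). Fatigue and somnolence survive the BH
correction at this small sample size; dizziness (planted ratio 1.45) and
disorientation do not, which is the expected power profile at n = 2,000.

The same pipeline is exposed on the command line:

```bash
claimscohort run-all --seed 7 --out out           # generate + analyze
claimscohort generate --seed 7 --out claims       # claims tables only
claimscohort build-cohorts --claims claims --out cohorts
claimscohort analyze --claims claims --n-boot 199 --seed 7 --out out
claimscohort report --results out/results.json
```

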