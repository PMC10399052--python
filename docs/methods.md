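# Methods

This note records the model, the conventions, and the design choices behind
`claimscohort`, in the spirit of a simulation-study methods section: what is
assumed, what is emulated, and what passing tests do and do not demonstrate.

## Data model and conventions

Claims are three tables — patients (sex, birth year, enrollment span),
dated ICD-10 diagnoses, dated drug-class prescriptions. All dates are
integer day indices from a dataset epoch (2015-10-01 by default; ISO dates
in input files are converted on read). Every interval in the package is
half-open `[start, end)`: the look-back is `[index − 365, index)` and
excludes the index day, windows are `[index, end)`. This removes all
off-by-one ambiguity from window arithmetic; boundary behavior is pinned by
tests (a code on the index day does not count as baseline history; exactly
50 repeats is not an outlier; a follow-up insomnia code exactly 183 days
after the last one does not extend the window).

ICD-10 matching is by normalized prefix (uppercase, dots stripped), with
the family convention that a prefix covers all of its children: `F510`
matches `F5101`. Within one code set no prefix may be a prefix of another,
preventing double counting. Medications are drug-class tokens rather than
NDC codes: the published medication list behind the treatment definition is
not reproducible from the available text, so the class vocabulary
(benzodiazepine, z_drug, trazodone, dora, ramelteon, tetracyclic,
tricyclic) is configurable, as are all code sets. Three code-set defaults
are explicit assumptions rather than sourced values: dizziness = R42,
sleep paralysis = G47.53, complex sleep-related behaviors = G47.52. The
fatigue set includes both R53.82 and R53.83 (the source material lists
"chronic fatigue" and "other fatigue" under a single code; standard ICD-10
places chronic fatigue at R53.82, so both are kept).

## Cohort construction

The untreated-insomnia window-end rule is implemented as a rolling chain:
each new insomnia code arriving strictly less than `gap_days` (183, the
"6 months" on a day grid) after the previous one extends the window;
`window_end = min(last_code + gap, first treatment after index,
enrollment end, data end)`. A treatment on or before the index date
disqualifies the patient from the untreated cohort entirely. One window per
patient per cohort (the first qualifying one) keeps the analysis unit
simple and avoids double-counting a patient within a cohort.

The control index is enrollment-anchored — the first day with a full
look-back of enrollment — rather than visit-anchored; with no baseline
visit structure in the data model this is the only well-defined reading,
and it is what the synthetic generator emulates. Exclusion screening
(pregnancy Z34/O*, palliative care Z51.5, malignancy C*, age < 18,
insufficient look-back) is applied at the candidate index in both cohorts.
A patient can contribute a control window first and an untreated-insomnia
window after a later diagnosis; the attrition log counts each
patient-treatment once per cohort, and its internal identity
`eligible_total = untreated + control` is asserted on every run.

The young-healthy subgroup (< 40 years, no chronic comorbidity in the
look-back) screens against a 16-set Charlson-style roster shipped as a
configurable default; the exact roster behind the published subgroup is not
recoverable, so it is a named, overridable list. Age is computed from birth
year at calendar-year resolution, the best claims data support.

## Endpoints

Rate endpoints count every (deduplicated) event; annualized occurrence is
the per-exposure-year share of units with at least one event; both are
`Σy / Σt` on the 100 patient-year scale with a 365.25-day year. Prevalence
endpoints address the mechanical advantage long windows give rare chronic
codes: every window keeps its first `reference_days / cohort-mean-duration`
fraction (capped at 1; truncated lengths floored to whole days with a
1-day minimum so exposure stays positive), and the truncated indicator mean
is normalized to one year by linear scaling `× 365.25 / reference_days`.
Linear scaling is the minimal reading of "normalized to 1 year" and is
isolated in one function should a refit-over-a-year definition ever be
preferred. `reference_days` defaults to 131 — the mean treated-cohort
window of the motivating study, the smallest of the three cohort means —
and the fractions are recomputed from the data at run time (the reported
means 211 and 895 days reproduce the published 62% and 15% retained
fractions, which the acceptance checks pin).

The truncation plan is computed once from the full sample and reused inside
the bootstrap; resampling perturbs cohort mean durations by well under 1%
at the sizes analyzed, and freezing the plan keeps per-unit responses fixed
so only weights are re-estimated per resample.

## Estimation and inference

The propensity model is unpenalized logistic regression (scikit-learn's
Newton–Cholesky solver with a vanishing ridge, `C = 1e8`, which only
stabilizes separable or singular bootstrap resamples) on standardized age,
sex, and the 0/1 comorbidity flags; constant columns are dropped; fitted
scores are clipped to `[1e−6, 1 − 1e−6]` so weights stay finite under
positivity violations without touching well-behaved scores. ATE weights
`1/p` and `1/(1−p)` are used because the estimand is the average treatment
effect over the combined patient-treatment population; symmetric weight
trimming exists but defaults off.

Bootstrap inference resamples patient-treatments with replacement within
the analysis set of each subgroup and **refits the propensity model in
every resample**, so weight-estimation uncertainty propagates into both the
balance diagnostics and the ATE distribution. Resamples that lose a whole
cohort are recorded as missing and excluded from percentiles (they do not
occur at the default sizes). P-values use the add-one tail count
`2·min(#{b ≤ 0}+1, #{b ≥ 0}+1)/(n_boot+1)` capped at 1 — the smallest
attainable value is `2/(n_boot+1)`, a deliberate discreteness floor
(≈ 0.0039 at the default 512 resamples). CIs are plain 2.5/97.5
percentiles. Balance uses the weighted standardized difference
`|m₁ − m₂| / sqrt((s₁² + s₂²)/2)` with weighted population variances; a
covariate is balanced when the 95th percentile of its bootstrapped values
is below 0.15, and a sample is balanced when all covariates are.
Benjamini–Hochberg adjustment (via statsmodels, cross-checked in tests
against a direct implementation of the step-up definition) runs across the
entire endpoint × subgroup grid of one run.

With all weights equal to 1, the weighted exposure estimator reduces
exactly to the unweighted cohort summary; this identity is a test.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any vendor's schema. Per patient: independent Bernoulli baseline
comorbidity flags (default prevalences shaped like a large US non-insomnia
claims population, e.g. hypertension 26.3%, anxiety 8.5%); latent insomnia
from a logistic model on those flags (the planted confounding; intercept
calibrated so the marginal sits near the target 14.3%); a gamma-distributed
enrollment span (mean 1,200 days, minimum 500) inside a ~4.5-year data
window; an insomnia diagnosis shortly after full look-back coverage, with
Poisson follow-up codes that chain the rolling window; a treatment
prescription for a configurable share of insomniacs; and outcome diagnoses
from a memoryless (exponential inter-arrival) event process at yearly rate

```
lambda = base_rate × effect^{1[insomnia, post-diagnosis]} × Π_j c_j^{x_j}
```

The rate ratio applies **from the first insomnia diagnosis onward**: the
planted burden is post-onset, which is what the observation windows
measure, and it keeps an insomniac's pre-diagnosis control window at
baseline rates so double cohort membership does not contaminate the control
cohort. Because the same flags shift insomnia odds and outcome rates, the
unweighted cohort contrast is confounded upward by construction while the
IPTW contrast targets the analytic ATE

```
ATE = base × (effect − 1) × Π_j (1 − p_j + p_j c_j) × 100   per 100 PY,
```

which `GroundTruth` computes in closed form from the configuration. Cleaning
targets are injected on top: same-day duplicate claims (probability 0.05
per event) and rare outlier patients with 55 disorientation repeats on
distinct look-back days (probability 0.001). An unmeasured-confounder
switch exists for robustness experiments and defaults off, so
exchangeability holds by construction.

What the generator does **not** emulate: coding intensity drift, visit
structure, billing artifacts beyond duplicates/outliers, treatment
switching, calendar seasonality, or outcome rates that depend on age and
sex (both enter the propensity design but are independent of insomnia by
default). Passing the validation therefore shows the estimation chain is
correct under its own assumptions — exchangeability given the observed
flags, positivity, a correctly specified logistic propensity — not that
those assumptions hold in any real claims source.

## Validation experiments and problem sizes

The recovery experiment (`claimscohort.validation`) uses ≈ 5,000
patient-treatments per cohort, three confounders (insomnia log-odds 1.2 /
1.0 / 0.8; outcome rate multipliers 1.8 / 1.5 / 1.3), a fatigue-like rate
endpoint at 0.19 events/person-year with planted ratio 2.5 (analytic ATE
≈ 41/100 PY), diagnosis immediately at look-back completion (disjoint
cohorts, so the pooled analysis population equals the generated one), and
199 bootstrap resamples per replicate for the replicate loops. Across 100
replicates the 95% CI covers the truth in ≥ 90%, the unweighted contrast is
biased upward by ≈ +10/100 PY, and IPTW removes most of that bias. The null
calibration (all ratios 1, confounding on, 3,000 patients, 50 replicates)
keeps the BH-adjusted rejection rate at or below 0.07. Full-pipeline
determinism is checked byte-for-byte on 2,000 patients. These sizes are the
package's validation design; all are configurable.

## Known limitations

* Balance verdicts at small n are conservative: for rare flags (< 1%
  prevalence) the 95th bootstrap percentile of the standardized difference
  exceeds 0.15 from sampling noise alone, so a 2,000-patient run reports
  "unbalanced" covariates that a 100k-patient run would not.
* The prevalence one-year normalization is linear in exposure; rare-event
  prevalences well above ~30% per window would make that approximation
  visible.
* Emergency-room visits are procedure-coded in real claims; the shipped
  endpoint roster covers diagnosis-coded endpoints only (falls and
  injuries use external-cause prefixes W0*/W1* and S*/T*).
* The weighted rate estimator is a ratio estimator; its O(1/n) small-sample
  bias is negligible at the validated sizes but untested below a few
  hundred units per cohort.
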