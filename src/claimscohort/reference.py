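"""Benchmark constants reported by the motivating large US claims study.

The study's patient-level data are proprietary, but a handful of its printed
summary numbers are self-contained arithmetic consequences of the design and
serve as fixed-point checks of this package's cohort logic: the cohort sizes
and their eligible total, the female share of the exposure cohort, and the
mean observation-window durations that fix the prevalence truncation
fractions. Nothing here is used as an analysis input for synthetic runs.
"""

UNTREATED_COHORT_N = 139_959
NON_INSOMNIA_COHORT_N = 836_975
ELIGIBLE_TOTAL = 976_934

UNTREATED_FEMALE_N = 85_375
UNTREATED_FEMALE_PCT = 61.0

#: Mean observation-window durations (days) per cohort; the treated-cohort
#: mean (131 d) is the truncation reference for prevalence endpoints.
MEAN_DURATION_DAYS = {
    "treated": 131.0,
    "untreated_insomnia": 211.0,
    "non_insomnia": 895.0,
}

#: Retained window fractions the truncation plan should reproduce (printed
#: as 62% and 15%).
TRUNCATION_FRACTION_PCT = {
    "untreated_insomnia": 62.0,
    "non_insomnia": 15.0,
}
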