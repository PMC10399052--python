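"""Cohort construction: eligibility, observation windows, covariates, subgroups.

Two cohorts are built from the same claims population:

* **untreated insomnia** — index date is the first qualifying insomnia
  diagnosis; the observation window rolls forward while further insomnia
  codes arrive less than ``gap_days`` (default 183, the "6 months") apart,
  and closes at the earlier of the gap expiring, the first insomnia
  treatment, or the end of enrollment/data. A treatment on or before the
  index date disqualifies the patient from this cohort entirely.
* **non-insomnia** — index date is the first day with a full look-back of
  enrollment; any insomnia diagnosis, circadian-rhythm diagnosis or insomnia
  treatment on or before that day disqualifies; the first such event after
  the index closes the window.

A patient may legitimately appear in both cohorts (control window first,
untreated-insomnia window after a later diagnosis), each contributing its
own patient-treatment, which is the unit of all downstream analysis.

Eligibility everywhere: age >= 18 at index, a full ``lookback_days`` of
enrollment before the index, and no pregnancy / palliative-care / active-
malignancy code during the look-back. Intervals are half-open ``[start,
end)``: the look-back is ``[index - lookback_days, index)`` and excludes the
index day itself.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codes_io import (
    BASELINE_COVARIATES,
    CHARLSON_SETS,
    DEFAULT_TREATMENT_CLASSES,
    DIAGNOSIS,
    EPOCH,
    FEMALE,
    PRESCRIPTION,
    CodeSet,
    PatientRecord,
    build_code_sets,
    deduplicate_same_day,
    matches,
)
from .exceptions import ConfigError

UNTREATED_INSOMNIA = "untreated_insomnia"
NON_INSOMNIA = "non_insomnia"
COHORTS = (UNTREATED_INSOMNIA, NON_INSOMNIA)

SUBGROUPS = ("full_population", "young_healthy", "female_40_55", "elderly_65plus")


@dataclass
class StudyConfig:
    """Constants of the cohort design, all user-overridable."""

    lookback_days: int = 365
    gap_days: int = 183  # "6 months" on the day grid
    outlier_threshold: int = 50
    min_age: int = 18
    data_end: int | None = None  # day index past the last collected claim
    epoch: _dt.date = EPOCH
    code_sets: dict[str, CodeSet] = field(default_factory=build_code_sets)
    treatment_classes: frozenset[str] = DEFAULT_TREATMENT_CLASSES
    baseline_covariates: tuple[str, ...] = BASELINE_COVARIATES
    exclusion_sets: tuple[str, ...] = ("pregnancy", "palliative_care", "malignancy")
    charlson_sets: tuple[str, ...] = CHARLSON_SETS

    def __post_init__(self) -> None:
        for name, value in (
            ("lookback_days", self.lookback_days),
            ("gap_days", self.gap_days),
            ("outlier_threshold", self.outlier_threshold),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name in (
            self.exclusion_sets + self.charlson_sets + self.baseline_covariates
        ):
            if name not in self.code_sets:
                raise ConfigError(f"unknown code set {name!r} in study config")


@dataclass(frozen=True)
class PatientTreatment:
    """One cohort-membership episode — the analysis unit.

    ``duration_days = window_end - index_date`` is the exposure the endpoint
    metrics divide by; ``lookback_start = index_date - lookback_days`` bounds
    the covariate/exclusion scan.
    """

    patient_id: str
    cohort: str
    index_date: int
    window_end: int
    lookback_start: int

    def __post_init__(self) -> None:
        if self.window_end <= self.index_date:
            raise ConfigError(
                f"window_end {self.window_end} must exceed index {self.index_date}"
            )
        if self.cohort not in COHORTS:
            raise ConfigError(f"unknown cohort {self.cohort!r}")

    @property
    def duration_days(self) -> int:
        return self.window_end - self.index_date


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline covariates at the index date: age, sex, look-back flags.

    Flags are presence indicators (>=1 matching diagnosis in the look-back),
    so missingness is structurally impossible. ``charlson_any`` records
    whether any Charlson-roster condition appeared in the look-back; it feeds
    the young-healthy subgroup screen, not the propensity design.
    """

    age_at_index: int
    sex: str
    flags: Mapping[str, bool]
    charlson_any: bool


@dataclass(frozen=True)
class SubgroupAssignment:
    full_population: bool
    young_healthy: bool
    female_40_55: bool
    elderly_65plus: bool

    def as_dict(self) -> dict[str, bool]:
        return {
            "full_population": self.full_population,
            "young_healthy": self.young_healthy,
            "female_40_55": self.female_40_55,
            "elderly_65plus": self.elderly_65plus,
        }


def age_at(patient: PatientRecord, day: int, config: StudyConfig) -> int:
    """Age in whole years at a day index, at birth-year resolution
    (claims carry no birth month/day)."""
    year = (config.epoch + _dt.timedelta(days=int(day))).year
    return year - patient.birth_year


def apply_exclusions(
    patient: PatientRecord, candidate_index: int, config: StudyConfig
) -> str | None:
    """Eligibility screen at a candidate index date.

    Returns ``None`` on acceptance, or a rejection-reason string:
    ``insufficient_lookback``, ``underage``, or ``excluded_<set>`` when an
    exclusion code set matches during the look-back. Rejection is a value,
    not an error.
    """
    if candidate_index - patient.enroll_start < config.lookback_days:
        return "insufficient_lookback"
    if age_at(patient, candidate_index, config) < config.min_age:
        return "underage"
    lb_start = candidate_index - config.lookback_days
    for set_name in config.exclusion_sets:
        cset = config.code_sets[set_name]
        for e in patient.events:
            if (
                e.kind == DIAGNOSIS
                and lb_start <= e.date < candidate_index
                and matches(cset, e.code)
            ):
                return f"excluded_{set_name}"
    return None


def _insomnia_dx_dates(patient: PatientRecord, config: StudyConfig) -> list[int]:
    cset = config.code_sets["insomnia_dx"]
    return sorted(
        {e.date for e in patient.events if e.kind == DIAGNOSIS and matches(cset, e.code)}
    )


def _circadian_dx_dates(patient: PatientRecord, config: StudyConfig) -> list[int]:
    cset = config.code_sets["circadian"]
    return sorted(
        {e.date for e in patient.events if e.kind == DIAGNOSIS and matches(cset, e.code)}
    )


def _treatment_dates(patient: PatientRecord, config: StudyConfig) -> list[int]:
    return sorted(
        {
            e.date
            for e in patient.events
            if e.kind == PRESCRIPTION and e.code in config.treatment_classes
        }
    )


def _data_end(patient: PatientRecord, config: StudyConfig) -> int:
    return (
        patient.enroll_end
        if config.data_end is None
        else min(patient.enroll_end, config.data_end)
    )


def _untreated_window(
    patient: PatientRecord, config: StudyConfig
) -> tuple[PatientTreatment | None, str | None]:
    dx_dates = _insomnia_dx_dates(patient, config)
    if not dx_dates:
        return None, "no_insomnia_diagnosis"
    rx_dates = _treatment_dates(patient, config)
    reason = None
    for index in dx_dates:
        reason = apply_exclusions(patient, index, config)
        if reason is None:
            break
    else:
        return None, reason
    if any(d <= index for d in rx_dates):
        return None, "treated"
    first_rx = min((d for d in rx_dates if d > index), default=None)
    rx_bound = first_rx if first_rx is not None else float("inf")

    last = index
    for d in dx_dates:
        if d <= index or d >= rx_bound:
            continue
        if d - last < config.gap_days:
            last = d
        else:
            break
    end = min(last + config.gap_days, _data_end(patient, config))
    if first_rx is not None:
        end = min(end, first_rx)
    if end <= index:
        return None, "empty_window"
    return (
        PatientTreatment(
            patient_id=patient.patient_id,
            cohort=UNTREATED_INSOMNIA,
            index_date=index,
            window_end=end,
            lookback_start=index - config.lookback_days,
        ),
        None,
    )


def build_untreated_insomnia_window(
    patient: PatientRecord, config: StudyConfig
) -> PatientTreatment | None:
    """Untreated-insomnia patient-treatment, or ``None`` if the patient
    never qualifies (no eligible diagnosis, or treated on/before index)."""
    return _untreated_window(patient, config)[0]


def _non_insomnia_window(
    patient: PatientRecord, config: StudyConfig
) -> tuple[PatientTreatment | None, str | None]:
    index = patient.enroll_start + config.lookback_days
    disqualifiers = (
        _insomnia_dx_dates(patient, config)
        + _circadian_dx_dates(patient, config)
        + _treatment_dates(patient, config)
    )
    if any(d <= index for d in disqualifiers):
        return None, "insomnia_history"
    reason = apply_exclusions(patient, index, config)
    if reason is not None:
        return None, reason
    end = min(
        [_data_end(patient, config)] + [d for d in disqualifiers if d > index]
    )
    if end <= index:
        return None, "empty_window"
    return (
        PatientTreatment(
            patient_id=patient.patient_id,
            cohort=NON_INSOMNIA,
            index_date=index,
            window_end=end,
            lookback_start=patient.enroll_start,
        ),
        None,
    )


def build_non_insomnia_window(
    patient: PatientRecord, config: StudyConfig
) -> PatientTreatment | None:
    """Non-insomnia (control) patient-treatment, or ``None``.

    The index is enrollment-anchored: the first day with a full look-back of
    enrollment. Any insomnia/circadian diagnosis or insomnia treatment on or
    before that day disqualifies; the first one after it ends the window.
    """
    return _non_insomnia_window(patient, config)[0]


def remove_outlier_samples(
    treatments: Sequence[PatientTreatment],
    patients: Mapping[str, PatientRecord],
    config: StudyConfig,
) -> list[PatientTreatment]:
    """Drop patient-treatments whose look-back holds more than
    ``outlier_threshold`` deduplicated disorientation or sleep-paralysis
    diagnoses (strict inequality: exactly 50 is retained)."""
    sets = [config.code_sets["disorientation"], config.code_sets["sleep_paralysis"]]
    kept = []
    for t in treatments:
        patient = patients[t.patient_id]
        events = deduplicate_same_day(patient.events)
        outlier = False
        for cset in sets:
            count = sum(
                1
                for e in events
                if e.kind == DIAGNOSIS
                and t.lookback_start <= e.date < t.index_date
                and matches(cset, e.code)
            )
            if count > config.outlier_threshold:
                outlier = True
                break
        if not outlier:
            kept.append(t)
    return kept


def extract_covariates(
    treatment: PatientTreatment, patient: PatientRecord, config: StudyConfig
) -> CovariateProfile:
    """Baseline covariates over ``[lookback_start, index_date)``."""
    flags = {}
    lb, idx = treatment.lookback_start, treatment.index_date
    dx_in_lookback = [
        e for e in patient.events if e.kind == DIAGNOSIS and lb <= e.date < idx
    ]
    for name in config.baseline_covariates:
        cset = config.code_sets[name]
        flags[name] = any(matches(cset, e.code) for e in dx_in_lookback)
    charlson_any = any(
        matches(config.code_sets[name], e.code)
        for name in config.charlson_sets
        for e in dx_in_lookback
    )
    return CovariateProfile(
        age_at_index=age_at(patient, idx, config),
        sex=patient.sex,
        flags=flags,
        charlson_any=charlson_any,
    )


def assign_subgroups(profile: CovariateProfile) -> SubgroupAssignment:
    """Subgroup membership: everyone is in the full population; young-healthy
    means age < 40 with no Charlson-roster condition in the look-back."""
    age = profile.age_at_index
    return SubgroupAssignment(
        full_population=True,
        young_healthy=age < 40 and not profile.charlson_any,
        female_40_55=profile.sex == FEMALE and 40 <= age <= 55,
        elderly_65plus=age >= 65,
    )


def build_cohorts(
    patients: Iterable[PatientRecord], config: StudyConfig
) -> tuple[list[PatientTreatment], Counter]:
    """Build both cohorts over a population and tally attrition reasons.

    Returns the outlier-filtered patient-treatments and a counter with one
    entry per rejection reason plus ``untreated_insomnia``, ``non_insomnia``,
    ``outlier_removed`` and the internal-consistency total
    ``eligible_total = untreated_insomnia + non_insomnia``.
    """
    patients = list(patients)
    by_id = {p.patient_id: p for p in patients}
    attrition: Counter = Counter()
    attrition["patients_total"] = len(patients)
    treatments: list[PatientTreatment] = []
    for p in patients:
        t, reason = _untreated_window(p, config)
        if t is not None:
            treatments.append(t)
        elif reason != "no_insomnia_diagnosis":
            attrition[f"untreated_reject_{reason}"] += 1
        t, reason = _non_insomnia_window(p, config)
        if t is not None:
            treatments.append(t)
        elif reason != "insomnia_history":
            attrition[f"control_reject_{reason}"] += 1
        else:
            attrition["control_reject_insomnia_history"] += 1
    kept = remove_outlier_samples(treatments, by_id, config)
    attrition["outlier_removed"] = len(treatments) - len(kept)
    attrition[UNTREATED_INSOMNIA] = sum(
        1 for t in kept if t.cohort == UNTREATED_INSOMNIA
    )
    attrition[NON_INSOMNIA] = sum(1 for t in kept if t.cohort == NON_INSOMNIA)
    attrition["eligible_total"] = eligible_total(attrition)
    return kept, attrition


def eligible_total(cohort_counts: Mapping[str, int]) -> int:
    """Attrition-log identity: the eligible patient-treatment total is the
    sum of the per-cohort counts (a patient present in both cohorts counts
    once per cohort)."""
    return int(cohort_counts[UNTREATED_INSOMNIA]) + int(cohort_counts[NON_INSOMNIA])
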