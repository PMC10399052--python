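"""Endpoint metrics: rate, annualized occurrence, and truncated prevalence.

Each endpoint is a named ICD-10 code set plus a metric kind. A
patient-treatment contributes one unit response ``(y_i, t_i)``:

* ``rate`` — ``y`` = number of matching (deduplicated) diagnoses inside the
  observation window, ``t`` = window duration in years. Used for acute,
  repeatable events (the daytime-impairment endpoints, falls, injuries).
* ``annualized_occurrence`` — ``y`` = 1 if at least one match, ``t`` =
  duration in years. Used for common chronic conditions, where repeat codes
  reflect billing, not new disease.
* ``prevalence`` — windows are first truncated to a common reference
  duration (see :class:`TruncationPlan`), then ``y`` = 1 if a match falls in
  the truncated window and ``t`` is the truncated duration. Used for rare
  chronic conditions, where longer windows mechanically inflate the chance
  of observing a code.

Cohort summaries are ``sum(y)/sum(t) * 100`` per 100 patient-years for the
two exposure metrics, and for prevalence the mean indicator rescaled to a
one-year horizon (``* 365.25 / reference_days``) and then to the 100
patient-year scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .codes_io import DIAGNOSIS, CodeSet, PatientRecord, deduplicate_same_day, matches
from .cohorts import COHORTS, PatientTreatment
from .exceptions import ConfigError, EstimationError

DAYS_PER_YEAR = 365.25

RATE = "rate"
ANNUALIZED = "annualized_occurrence"
PREVALENCE = "prevalence"
METRICS = (RATE, ANNUALIZED, PREVALENCE)


@dataclass(frozen=True)
class EndpointSpec:
    """A named outcome: code set plus metric kind."""

    name: str
    code_set: CodeSet
    metric: str

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigError(f"unknown metric {self.metric!r} for {self.name!r}")


#: Shipped endpoint roster: (name, code-set name, metric). Daytime
#: impairments and acute events as rates; common chronic conditions as
#: annualized occurrence; rare chronic conditions as prevalence.
DEFAULT_ENDPOINT_ROSTER: tuple[tuple[str, str, str], ...] = (
    ("disorientation", "disorientation", RATE),
    ("dizziness", "dizziness", RATE),
    ("fatigue", "fatigue", RATE),
    ("somnolence", "somnolence", RATE),
    ("complex_sleep_behaviors", "complex_sleep_behaviors", RATE),
    ("falls", "falls", RATE),
    ("injury_poisoning", "injury_poisoning", RATE),
    ("alcohol_drug_abuse", "alcohol_drug_abuse", ANNUALIZED),
    ("anxiety", "anxiety", ANNUALIZED),
    ("arterial_hypertension", "arterial_hypertension", ANNUALIZED),
    ("cerebral_infarction", "cerebral_infarction", ANNUALIZED),
    ("copd", "copd", ANNUALIZED),
    ("depression", "depression", ANNUALIZED),
    ("diabetes", "diabetes", ANNUALIZED),
    ("heart_failure", "heart_failure", ANNUALIZED),
    ("ischemic_heart_disease", "ischemic_heart_disease", ANNUALIZED),
    ("obesity", "obesity", ANNUALIZED),
    ("obstructive_sleep_apnea", "obstructive_sleep_apnea", ANNUALIZED),
    ("dementia", "dementia", PREVALENCE),
    ("metabolic_syndrome", "metabolic_syndrome", PREVALENCE),
)


def default_endpoints(code_sets: Mapping[str, CodeSet]) -> list[EndpointSpec]:
    return [
        EndpointSpec(name=name, code_set=code_sets[set_name], metric=metric)
        for name, set_name, metric in DEFAULT_ENDPOINT_ROSTER
    ]


@dataclass(frozen=True)
class UnitResponse:
    """One patient-treatment's contribution ``(y, t)`` to an endpoint."""

    treatment: PatientTreatment
    y: float
    t: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise EstimationError("unit exposure t must be positive")


@dataclass(frozen=True)
class TruncationPlan:
    """Per-cohort window truncation for prevalence endpoints.

    Cohorts differ hugely in typical window length, and for a rare chronic
    condition a longer window mechanically raises the chance of seeing its
    code. Each cohort's windows are therefore cut to the same reference
    duration *in expectation*: every window keeps its first
    ``reference_days / mean_duration(cohort)`` fraction (capped at 1).
    ``reference_days`` defaults to 131 — the typical treated-cohort window
    in the motivating study, the smallest of the three cohort means.
    """

    reference_days: float = 131.0
    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_days <= 0:
            raise ConfigError("reference_days must be positive")
        for cohort, f in self.fractions.items():
            if not (0.0 < f <= 1.0):
                raise ConfigError(
                    f"truncation fraction for {cohort!r} must be in (0, 1], got {f}"
                )

    @classmethod
    def from_mean_durations(
        cls, mean_days: Mapping[str, float], reference_days: float = 131.0
    ) -> "TruncationPlan":
        fractions = {
            cohort: min(1.0, reference_days / mean)
            for cohort, mean in mean_days.items()
        }
        return cls(reference_days=reference_days, fractions=fractions)

    @classmethod
    def from_treatments(
        cls, treatments: Sequence[PatientTreatment], reference_days: float = 131.0
    ) -> "TruncationPlan":
        means = {}
        for cohort in COHORTS:
            durations = [t.duration_days for t in treatments if t.cohort == cohort]
            if durations:
                means[cohort] = sum(durations) / len(durations)
        return cls.from_mean_durations(means, reference_days)

    def truncated_days(self, treatment: PatientTreatment) -> int:
        """Whole days retained for one window (floor; at least one day so
        every unit keeps positive exposure)."""
        frac = self.fractions.get(treatment.cohort, 1.0)
        return max(1, math.floor(frac * treatment.duration_days))


def unit_responses(
    treatments: Sequence[PatientTreatment],
    spec: EndpointSpec,
    patients: Mapping[str, PatientRecord],
    plan: TruncationPlan | None = None,
) -> list[UnitResponse]:
    """Per-unit responses for one endpoint across patient-treatments."""
    if spec.metric == PREVALENCE and plan is None:
        raise ConfigError(
            f"prevalence endpoint {spec.name!r} requires a TruncationPlan"
        )
    out = []
    for t in treatments:
        patient = patients[t.patient_id]
        events = deduplicate_same_day(patient.events)
        if spec.metric == PREVALENCE:
            end = t.index_date + plan.truncated_days(t)
        else:
            end = t.window_end
        count = sum(
            1
            for e in events
            if e.kind == DIAGNOSIS
            and t.index_date <= e.date < end
            and matches(spec.code_set, e.code)
        )
        exposure_days = end - t.index_date
        y = float(count) if spec.metric == RATE else float(count >= 1)
        out.append(UnitResponse(treatment=t, y=y, t=exposure_days / DAYS_PER_YEAR))
    return out


def cohort_summary_unweighted(
    responses: Sequence[UnitResponse],
    metric: str,
    reference_days: float | None = None,
) -> float:
    """Unweighted cohort summary on the 100 patient-year scale.

    Rate and annualized occurrence: ``sum(y) / sum(t) * 100``. Prevalence:
    ``mean(y) * (365.25 / reference_days) * 100`` (the linear one-year
    normalization of the truncated-window indicator).
    """
    if not responses:
        raise EstimationError("cannot summarize an empty response set")
    if metric == PREVALENCE:
        if reference_days is None or reference_days <= 0:
            raise ConfigError("prevalence summary requires positive reference_days")
        mean_y = sum(r.y for r in responses) / len(responses)
        return mean_y * (DAYS_PER_YEAR / reference_days) * 100.0
    total_t = sum(r.t for r in responses)
    if total_t <= 0:
        raise EstimationError("total exposure is zero")
    return sum(r.y for r in responses) / total_t * 100.0
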