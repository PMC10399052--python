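"""Endpoint metrics: unit responses, truncation, per-100-PY summaries."""

from __future__ import annotations

import random

import numpy as np
import pytest

from claimscohort import (
    EndpointSpec,
    StudyConfig,
    TruncationPlan,
    cohort_summary_unweighted,
    unit_responses,
)
from claimscohort.cohorts import NON_INSOMNIA, UNTREATED_INSOMNIA, PatientTreatment
from claimscohort.codes_io import CodeSet
from claimscohort.endpoints import ANNUALIZED, DAYS_PER_YEAR, PREVALENCE, RATE
from claimscohort.exceptions import ConfigError, EstimationError

FATIGUE = CodeSet("fatigue", frozenset({"R5382", "R5383"}))


def _treatment(pid="P1", cohort=UNTREATED_INSOMNIA, index=0, end=365):
    return PatientTreatment(
        patient_id=pid, cohort=cohort, index_date=index, window_end=end,
        lookback_start=index - 365,
    )


class TestTruncationPlan:
    def test_reference_fractions_from_reported_mean_durations(self):
        plan = TruncationPlan.from_mean_durations(
            {UNTREATED_INSOMNIA: 211.0, NON_INSOMNIA: 895.0}, reference_days=131.0
        )
        assert plan.fractions[UNTREATED_INSOMNIA] == pytest.approx(131 / 211)
        assert plan.fractions[NON_INSOMNIA] == pytest.approx(131 / 895)
        # the fractions round to the published 62% and 15%
        assert round(plan.fractions[UNTREATED_INSOMNIA] * 100) == 62
        assert round(plan.fractions[NON_INSOMNIA] * 100) == 15

    def test_reference_beyond_mean_caps_at_one(self):
        plan = TruncationPlan.from_mean_durations(
            {UNTREATED_INSOMNIA: 100.0}, reference_days=131.0
        )
        assert plan.fractions[UNTREATED_INSOMNIA] == 1.0

    def test_from_treatments_uses_cohort_means(self):
        treatments = [
            _treatment("A", UNTREATED_INSOMNIA, 365, 365 + 100),
            _treatment("B", UNTREATED_INSOMNIA, 365, 365 + 300),
            _treatment("C", NON_INSOMNIA, 365, 365 + 800),
        ]
        plan = TruncationPlan.from_treatments(treatments, reference_days=131.0)
        assert plan.fractions[UNTREATED_INSOMNIA] == pytest.approx(131 / 200)
        assert plan.fractions[NON_INSOMNIA] == pytest.approx(131 / 800)

    def test_truncated_days_floor_and_positive(self):
        plan = TruncationPlan.from_mean_durations(
            {UNTREATED_INSOMNIA: 895.0}, reference_days=131.0
        )
        t = _treatment(end=5)  # 5-day window, fraction ~0.146 -> floor 0 -> 1
        assert plan.truncated_days(t) == 1


class TestUnitResponses:
    def test_rate_counts_deduplicated_events_in_window(self, make_patient, dx):
        p = make_patient(
            enroll_start=0, enroll_end=1000,
            events=[dx(10, "R5382"), dx(10, "R5382"), dx(200, "R5383"), dx(400, "R5382")],
        )
        t = _treatment(index=0, end=365)
        spec = EndpointSpec("fatigue", FATIGUE, RATE)
        [r] = unit_responses([t], spec, {p.patient_id: p})
        assert r.y == 2  # same-day duplicate collapsed; day-400 event outside
        assert r.t == pytest.approx(365 / DAYS_PER_YEAR)

    def test_annualized_is_indicator(self, make_patient, dx):
        p = make_patient(events=[dx(10, "R5382"), dx(20, "R5382")])
        spec = EndpointSpec("fatigue", FATIGUE, ANNUALIZED)
        [r] = unit_responses([_treatment(index=0, end=365)], spec, {p.patient_id: p})
        assert r.y == 1.0

    def test_prevalence_requires_plan(self, make_patient):
        p = make_patient()
        spec = EndpointSpec("fatigue", FATIGUE, PREVALENCE)
        with pytest.raises(ConfigError):
            unit_responses([_treatment()], spec, {p.patient_id: p}, plan=None)

    def test_prevalence_truncation_shrinks_window(self, make_patient, dx):
        # event at day 300 of a 365-day window; untreated fraction 131/211
        # keeps floor(0.62*365)=226 days, so the event falls outside
        p = make_patient(events=[dx(300, "R5382")])
        plan = TruncationPlan.from_mean_durations(
            {UNTREATED_INSOMNIA: 211.0}, reference_days=131.0
        )
        spec = EndpointSpec("fatigue", FATIGUE, PREVALENCE)
        [r] = unit_responses([_treatment(index=0, end=365)], spec, {p.patient_id: p}, plan)
        assert r.y == 0.0
        assert r.t == pytest.approx(226 / DAYS_PER_YEAR)

    def test_truncation_never_increases_y_or_t(self, make_patient, dx):
        rng = random.Random(2)
        for i in range(100):
            n_events = rng.randrange(0, 5)
            events = [dx(rng.randrange(0, 400), "R5382") for _ in range(n_events)]
            p = make_patient(patient_id=f"P{i}", events=events)
            t = _treatment(pid=f"P{i}", index=0, end=rng.randrange(30, 400))
            plan = TruncationPlan.from_mean_durations(
                {UNTREATED_INSOMNIA: rng.uniform(131, 900)}, 131.0
            )
            spec_prev = EndpointSpec("fatigue", FATIGUE, PREVALENCE)
            spec_ann = EndpointSpec("fatigue", FATIGUE, ANNUALIZED)
            [r_prev] = unit_responses([t], spec_prev, {t.patient_id: p}, plan)
            [r_ann] = unit_responses([t], spec_ann, {t.patient_id: p})
            assert r_prev.y <= r_ann.y
            assert r_prev.t <= r_ann.t

    def test_reference_at_or_above_mean_reduces_to_annualized_indicator(
        self, make_patient, dx
    ):
        p = make_patient(events=[dx(300, "R5382")])
        plan = TruncationPlan.from_mean_durations({UNTREATED_INSOMNIA: 100.0}, 131.0)
        spec_prev = EndpointSpec("fatigue", FATIGUE, PREVALENCE)
        spec_ann = EndpointSpec("fatigue", FATIGUE, ANNUALIZED)
        t = _treatment(index=0, end=365)
        [r_prev] = unit_responses([t], spec_prev, {p.patient_id: p}, plan)
        [r_ann] = unit_responses([t], spec_ann, {p.patient_id: p})
        assert (r_prev.y, r_prev.t) == (r_ann.y, r_ann.t)


class TestCohortSummary:
    def test_rate_five_events_over_two_patient_years(self, make_patient, dx):
        days = round(DAYS_PER_YEAR)  # 365 -> t=1.0 within a day's rounding
        p1 = make_patient(
            patient_id="A",
            events=[dx(d, "R5382") for d in (1, 2, 3)],
        )
        p2 = make_patient(patient_id="B", events=[dx(1, "R5382"), dx(2, "R5382")])
        treatments = [
            _treatment("A", index=0, end=days),
            _treatment("B", index=0, end=days),
        ]
        spec = EndpointSpec("fatigue", FATIGUE, RATE)
        responses = unit_responses(treatments, spec, {"A": p1, "B": p2})
        value = cohort_summary_unweighted(responses, RATE)
        assert value == pytest.approx(5 / (2 * days / DAYS_PER_YEAR) * 100)
        assert value == pytest.approx(250, rel=0.01)

    def test_all_zero_responses(self, make_patient):
        p = make_patient()
        spec = EndpointSpec("fatigue", FATIGUE, RATE)
        responses = unit_responses([_treatment()], spec, {p.patient_id: p})
        assert cohort_summary_unweighted(responses, RATE) == 0.0

    def test_empty_responses_error(self):
        with pytest.raises(EstimationError):
            cohort_summary_unweighted([], RATE)

    def test_prevalence_summary_normalizes_to_one_year(self, make_patient, dx):
        p1 = make_patient(patient_id="A", events=[dx(5, "R5382")])
        p2 = make_patient(patient_id="B")
        plan = TruncationPlan.from_mean_durations({UNTREATED_INSOMNIA: 211.0}, 131.0)
        spec = EndpointSpec("fatigue", FATIGUE, PREVALENCE)
        responses = unit_responses(
            [_treatment("A"), _treatment("B")], spec, {"A": p1, "B": p2}, plan
        )
        value = cohort_summary_unweighted(responses, PREVALENCE, reference_days=131.0)
        assert value == pytest.approx(0.5 * (DAYS_PER_YEAR / 131.0) * 100)

    def test_doubling_duration_halves_rate(self, make_patient, dx):
        p = make_patient(events=[dx(d, "R5382") for d in (1, 2, 3, 4)])
        spec = EndpointSpec("fatigue", FATIGUE, RATE)
        short = unit_responses([_treatment(index=0, end=200)], spec, {"P1": p})
        long = unit_responses([_treatment(index=0, end=400)], spec, {"P1": p})
        # same four events fall in both windows
        assert cohort_summary_unweighted(short, RATE) == pytest.approx(
            2 * cohort_summary_unweighted(long, RATE)
        )

    def test_matches_brute_force_recount_on_random_windows(self, make_patient, dx):
        rng = random.Random(17)
        patients, treatments = {}, []
        for i in range(50):
            events = [
                dx(rng.randrange(0, 600), rng.choice(["R5382", "R5383", "I10"]))
                for _ in range(rng.randrange(0, 12))
            ]
            pid = f"P{i}"
            patients[pid] = make_patient(patient_id=pid, events=events)
            start = rng.randrange(0, 200)
            treatments.append(
                _treatment(pid, index=start, end=start + rng.randrange(30, 400))
            )
        spec = EndpointSpec("fatigue", FATIGUE, RATE)
        responses = unit_responses(treatments, spec, patients)
        value = cohort_summary_unweighted(responses, RATE)
        # independent recount with plain python sets / sums
        total_events = 0
        total_years = 0.0
        for t in treatments:
            distinct = {
                (e.date, e.code)
                for e in patients[t.patient_id].events
                if e.code.startswith(("R5382", "R5383"))
                and t.index_date <= e.date < t.window_end
            }
            total_events += len(distinct)
            total_years += (t.window_end - t.index_date) / DAYS_PER_YEAR
        assert value == pytest.approx(total_events / total_years * 100)
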