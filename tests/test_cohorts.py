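"""Eligibility, observation windows, outlier removal, covariates, subgroups."""

from __future__ import annotations

import random

import pytest

from claimscohort import (
    StudyConfig,
    apply_exclusions,
    assign_subgroups,
    build_cohorts,
    build_non_insomnia_window,
    build_untreated_insomnia_window,
    extract_covariates,
    remove_outlier_samples,
)
from claimscohort.cohorts import NON_INSOMNIA, UNTREATED_INSOMNIA
from claimscohort.synthetic import SimulationConfig, generate_population

CFG = StudyConfig()


class TestApplyExclusions:
    def test_insufficient_lookback(self, make_patient):
        p = make_patient(enroll_start=200, enroll_end=1000)
        assert apply_exclusions(p, 400, CFG) == "insufficient_lookback"

    def test_underage(self, make_patient):
        # day 400 falls in 2016; born 1999 -> age 17
        p = make_patient(birth_year=1999)
        assert apply_exclusions(p, 400, CFG) == "underage"

    def test_accept(self, make_patient):
        p = make_patient(birth_year=1986)  # age 30 at day 400
        assert apply_exclusions(p, 400, CFG) is None

    @pytest.mark.parametrize(
        "code,reason",
        [("Z340", "excluded_pregnancy"), ("Z515", "excluded_palliative_care"),
         ("C50", "excluded_malignancy")],
    )
    def test_exclusion_codes_in_lookback(self, make_patient, dx, code, reason):
        p = make_patient(events=[dx(300, code)])
        assert apply_exclusions(p, 400, CFG) == reason

    def test_exclusion_code_on_index_day_ignored(self, make_patient, dx):
        # look-back is half-open [index - lookback, index)
        p = make_patient(events=[dx(400, "Z340")])
        assert apply_exclusions(p, 400, CFG) is None


class TestUntreatedInsomniaWindow:
    def test_single_dx_rolls_one_gap_forward(self, make_patient, dx):
        p = make_patient(events=[dx(400, "G4700")])
        t = build_untreated_insomnia_window(p, CFG)
        assert (t.index_date, t.window_end) == (400, 583)
        assert t.lookback_start == 35

    def test_treatment_truncates_window(self, make_patient, dx, rx):
        p = make_patient(events=[dx(400, "G4700"), rx(450, "z_drug"), dx(500, "G4700")])
        t = build_untreated_insomnia_window(p, CFG)
        assert (t.index_date, t.window_end) == (400, 450)

    def test_prior_treatment_disqualifies(self, make_patient, dx, rx):
        p = make_patient(events=[rx(100, "z_drug"), dx(400, "G4700")])
        assert build_untreated_insomnia_window(p, CFG) is None

    def test_same_day_treatment_disqualifies(self, make_patient, dx, rx):
        p = make_patient(events=[dx(400, "G4700"), rx(400, "trazodone")])
        assert build_untreated_insomnia_window(p, CFG) is None

    def test_chained_codes_extend_window(self, make_patient, dx):
        p = make_patient(events=[dx(400, "G4700"), dx(500, "F5101")])
        t = build_untreated_insomnia_window(p, CFG)
        assert t.window_end == 683  # 500 + 183

    def test_code_beyond_gap_does_not_extend(self, make_patient, dx):
        p = make_patient(enroll_end=2000, events=[dx(400, "G4700"), dx(583, "G4700")])
        t = build_untreated_insomnia_window(p, CFG)
        assert t.window_end == 583  # second code lands outside [400, 583)

    def test_window_clipped_to_enrollment(self, make_patient, dx):
        p = make_patient(enroll_end=500, events=[dx(400, "G4700")])
        t = build_untreated_insomnia_window(p, CFG)
        assert t.window_end == 500

    def test_no_insomnia_diagnosis(self, make_patient, dx):
        p = make_patient(events=[dx(400, "I10")])
        assert build_untreated_insomnia_window(p, CFG) is None

    def test_non_prescription_drug_does_not_count_as_treatment(
        self, make_patient, dx, rx
    ):
        p = make_patient(events=[dx(400, "G4700"), rx(450, "statin")])
        t = build_untreated_insomnia_window(p, CFG)
        assert t.window_end == 583


class TestNonInsomniaWindow:
    def test_clean_patient_enrollment_anchored(self, make_patient):
        t = build_non_insomnia_window(make_patient(), CFG)
        assert (t.index_date, t.window_end) == (365, 1000)
        assert t.lookback_start == 0

    def test_circadian_history_disqualifies(self, make_patient, dx):
        p = make_patient(events=[dx(50, "G4721")])
        assert build_non_insomnia_window(p, CFG) is None

    def test_later_insomnia_dx_ends_window_and_patient_joins_both_cohorts(
        self, make_patient, dx
    ):
        p = make_patient(events=[dx(600, "G4700")])
        control = build_non_insomnia_window(p, CFG)
        untreated = build_untreated_insomnia_window(p, CFG)
        assert (control.index_date, control.window_end) == (365, 600)
        assert (untreated.index_date, untreated.window_end) == (600, 783)

    def test_prior_treatment_disqualifies(self, make_patient, rx):
        p = make_patient(events=[rx(10, "benzodiazepine")])
        assert build_non_insomnia_window(p, CFG) is None

    def test_short_enrollment_yields_nothing(self, make_patient):
        p = make_patient(enroll_start=0, enroll_end=300)
        assert build_non_insomnia_window(p, CFG) is None


class TestOutlierRemoval:
    def _patient_with_repeats(self, make_patient, dx, n, code="R410"):
        # untreated window indexed at day 400; repeats on distinct look-back days
        events = [dx(400, "G4700")] + [dx(399 - i, code) for i in range(n)]
        return make_patient(events=events)

    @pytest.mark.parametrize("n,kept", [(51, 0), (50, 1)])
    def test_strict_threshold(self, make_patient, dx, n, kept):
        p = self._patient_with_repeats(make_patient, dx, n)
        t = build_untreated_insomnia_window(p, CFG)
        out = remove_outlier_samples([t], {p.patient_id: p}, CFG)
        assert len(out) == kept

    def test_sleep_paralysis_repeats_also_removed(self, make_patient, dx):
        p = self._patient_with_repeats(make_patient, dx, 51, code="G4753")
        t = build_untreated_insomnia_window(p, CFG)
        assert remove_outlier_samples([t], {p.patient_id: p}, CFG) == []

    def test_same_day_repeats_deduplicated_before_counting(self, make_patient, dx):
        # 60 claims on 30 distinct days -> 30 after dedup -> retained
        events = [dx(400, "G4700")]
        for i in range(30):
            events += [dx(399 - i, "R410"), dx(399 - i, "R410")]
        p = make_patient(events=events)
        t = build_untreated_insomnia_window(p, CFG)
        assert len(remove_outlier_samples([t], {p.patient_id: p}, CFG)) == 1

    def test_survivors_match_brute_force_recount(self, make_patient, dx):
        rng = random.Random(5)
        patients, treatments = {}, []
        for i in range(50):
            n_rep = rng.randrange(0, 80)
            events = [dx(400, "G4700")] + [dx(399 - j, "R410") for j in range(n_rep)]
            p = make_patient(patient_id=f"P{i}", events=events)
            patients[p.patient_id] = p
            treatments.append(build_untreated_insomnia_window(p, CFG))
        kept = remove_outlier_samples(treatments, patients, CFG)
        brute = [
            t
            for t in treatments
            if len(
                {
                    e.date
                    for e in patients[t.patient_id].events
                    if e.code.startswith("R410")
                    and t.lookback_start <= e.date < t.index_date
                }
            )
            <= 50
        ]
        assert kept == brute


class TestCovariatesAndSubgroups:
    def test_flag_inside_lookback(self, make_patient, dx):
        # hypertension code ten days before the index
        p = make_patient(events=[dx(355, "I10")])
        t = build_non_insomnia_window(p, CFG)
        prof = extract_covariates(t, p, CFG)
        assert prof.flags["arterial_hypertension"]

    def test_index_day_excluded_from_lookback(self, make_patient, dx):
        p = make_patient(events=[dx(365, "I10")])
        t = build_non_insomnia_window(p, CFG)
        prof = extract_covariates(t, p, CFG)
        assert not prof.flags["arterial_hypertension"]

    def test_flag_matrix_matches_brute_force_scan(self, make_patient, dx):
        rng = random.Random(11)
        codes = ["I10", "F41", "E66", "J44", "R52", "G4733"]
        expected_sets = {
            "I10": "arterial_hypertension", "F41": "anxiety", "E66": "obesity",
            "J44": "copd", "R52": "chronic_pain", "G4733": "obstructive_sleep_apnea",
        }
        for i in range(200):
            events = [
                (rng.randrange(0, 500), "diagnosis", rng.choice(codes))
                for _ in range(rng.randrange(0, 6))
            ]
            p = make_patient(patient_id=f"P{i}", events=events)
            t = build_non_insomnia_window(p, CFG)
            prof = extract_covariates(t, p, CFG)
            for code, set_name in expected_sets.items():
                brute = any(
                    c == code and 0 <= d < 365 for d, _, c in events
                )
                assert prof.flags[set_name] == brute, (i, code)

    def test_age_and_sex_subgroups(self, make_patient):
        cases = [
            (1982, "F", dict(young_healthy=True, female_40_55=False, elderly_65plus=False)),
            (1970, "F", dict(young_healthy=False, female_40_55=True, elderly_65plus=False)),
            (1946, "M", dict(young_healthy=False, female_40_55=False, elderly_65plus=True)),
            (1946, "F", dict(young_healthy=False, female_40_55=False, elderly_65plus=True)),
        ]
        for birth_year, sex, expected in cases:
            p = make_patient(birth_year=birth_year, sex=sex)
            t = build_non_insomnia_window(p, CFG)
            sub = assign_subgroups(extract_covariates(t, p, CFG)).as_dict()
            assert sub["full_population"]
            for key, value in expected.items():
                assert sub[key] == value, (birth_year, sex, key)

    def test_charlson_condition_blocks_young_healthy(self, make_patient, dx):
        p = make_patient(birth_year=1990, events=[dx(300, "E11")])  # diabetes
        t = build_non_insomnia_window(p, CFG)
        sub = assign_subgroups(extract_covariates(t, p, CFG))
        assert not sub.young_healthy


class TestCohortInvariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def synthetic_run():
        population, _ = generate_population(SimulationConfig(n_patients=600, seed=13))
        treatments, attrition = build_cohorts(population, CFG)
        return population, treatments, attrition

    def test_window_containment_and_lookback_coverage(self, synthetic_run):
        population, treatments, _ = synthetic_run
        by_id = {p.patient_id: p for p in population}
        for t in treatments:
            p = by_id[t.patient_id]
            assert t.duration_days > 0
            assert t.lookback_start >= p.enroll_start
            assert p.enroll_start <= t.index_date < t.window_end <= p.enroll_end

    def test_no_treatment_inside_untreated_window(self, synthetic_run):
        population, treatments, _ = synthetic_run
        by_id = {p.patient_id: p for p in population}
        for t in treatments:
            if t.cohort != UNTREATED_INSOMNIA:
                continue
            assert not any(
                t.index_date <= e.date < t.window_end
                for e in by_id[t.patient_id].prescriptions()
                if e.code in CFG.treatment_classes
            )

    def test_no_insomnia_dx_inside_control_window(self, synthetic_run):
        population, treatments, _ = synthetic_run
        by_id = {p.patient_id: p for p in population}
        insomnia = CFG.code_sets["insomnia_dx"]
        from claimscohort import matches

        for t in treatments:
            if t.cohort != NON_INSOMNIA:
                continue
            assert not any(
                matches(insomnia, e.code)
                for e in by_id[t.patient_id].diagnoses()
                if t.index_date <= e.date < t.window_end
            )

    def test_event_order_insensitive(self, make_patient, dx, rx):
        events = [dx(400, "G4700"), dx(500, "F5101"), rx(520, "z_drug"), dx(300, "I10")]
        p_sorted = make_patient(events=events)
        p_shuffled = make_patient(events=list(reversed(events)))
        a = build_untreated_insomnia_window(p_sorted, CFG)
        b = build_untreated_insomnia_window(p_shuffled, CFG)
        assert (a.index_date, a.window_end) == (b.index_date, b.window_end)

    def test_counts_match_independent_per_patient_scan(self, synthetic_run):
        population, treatments, attrition = synthetic_run
        brute = 0
        for p in population:
            built = [
                build_untreated_insomnia_window(p, CFG),
                build_non_insomnia_window(p, CFG),
            ]
            built = [t for t in built if t is not None]
            brute += len(remove_outlier_samples(built, {p.patient_id: p}, CFG))
        assert attrition["eligible_total"] == brute
        assert attrition["eligible_total"] == len(treatments)
        assert (
            attrition[UNTREATED_INSOMNIA] + attrition[NON_INSOMNIA]
            == attrition["eligible_total"]
        )
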