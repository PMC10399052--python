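"""Synthetic claims populations with known ground-truth cohort effects.

The generator emulates the statistical structure the downstream analysis
assumes: heterogeneous per-patient enrollment spans, confounded baseline
comorbidities, latent insomnia status driven by a logistic model on those
comorbidities, dated insomnia diagnosis codes (with optional treatment
prescriptions), and daytime-impairment outcome codes whose frequency depends
on latent insomnia status. Duplicate same-day claims and rare outlier
patients (>50 repeats of the disorientation code in a look-back year) are
injected so the cleaning rules have something to clean.

Ground truth is analytic, not empirical: outcome events follow a memoryless
(exponential inter-arrival, i.e. Poisson-count) process with per-patient
yearly rate

    lambda_i = base_rate * effect^{insomnia_i} * prod_j c_j^{x_ij}

where ``x_ij`` are the independent Bernoulli baseline flags and ``c_j`` the
configured covariate rate multipliers. The population-average treatment
effect on the 100 patient-year scale is then

    ATE = base_rate * (effect - 1) * prod_j (1 - p_j + p_j c_j) * 100,

which :class:`GroundTruth` records per endpoint. Because the same covariates
shift both insomnia odds and outcome rates, the unweighted cohort contrast is
confounded while the IPTW contrast targets the ATE — the parameter-recovery
surface the whole pipeline is validated against.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit, logit

from .codes_io import (
    DIAGNOSIS,
    PRESCRIPTION,
    FEMALE,
    MALE,
    ClaimEvent,
    PatientRecord,
    build_code_sets,
    write_claims,
)
from .exceptions import ConfigError

__all__ = ["SimulationConfig", "GroundTruth", "generate_population", "write_claims"]

DAYS_PER_YEAR = 365.25

#: Baseline flag prevalences shaped like the motivating study's non-insomnia
#: baseline column (fractions of patients with >=1 look-back diagnosis).
DEFAULT_PREVALENCES: dict[str, float] = {
    "alcohol_drug_abuse": 0.080,
    "chronic_pain": 0.042,
    "anxiety": 0.085,
    "depression": 0.081,
    "psychiatric_comorbidities": 0.132,
    "ptsd": 0.008,
    "schizophreniform": 0.008,
    "arterial_hypertension": 0.263,
    "cerebral_infarction": 0.007,
    "diabetes": 0.116,
    "heart_failure": 0.016,
    "ischemic_heart_disease": 0.044,
    "metabolic_syndrome": 0.005,
    "obesity": 0.111,
    "copd": 0.029,
    "obstructive_sleep_apnea": 0.044,
    "dementia": 0.005,
    "neurodegenerative": 0.017,
    "parkinsons": 0.002,
    "rls": 0.006,
}

#: Log-odds shifts of latent insomnia per baseline flag — the planted
#: confounding. Magnitudes chosen to reproduce the qualitative imbalance of
#: the motivating study's baseline table (anxiety/depression strongly
#: enriched, hypertension/obesity moderately).
DEFAULT_CONFOUNDER_EFFECTS: dict[str, float] = {
    "anxiety": 1.4,
    "depression": 1.2,
    "psychiatric_comorbidities": 0.9,
    "arterial_hypertension": 0.5,
    "obesity": 0.6,
    "obstructive_sleep_apnea": 1.0,
    "chronic_pain": 0.9,
    "alcohol_drug_abuse": 0.8,
}

#: Outcome base rates (events per person-year, non-insomnia stratum) and
#: multiplicative rate ratios under insomnia, shaped like the motivating
#: study's daytime-impairment rows (per-100-PY values / 100).
DEFAULT_OUTCOME_BASE_RATES: dict[str, float] = {
    "fatigue": 0.187,
    "dizziness": 0.103,
    "somnolence": 0.014,
    "disorientation": 0.007,
}
DEFAULT_OUTCOME_EFFECTS: dict[str, float] = {
    "fatigue": 2.5,
    "dizziness": 1.45,
    "somnolence": 4.0,
    "disorientation": 2.4,
}

#: Covariate -> outcome-rate multiplier (applied to every endpoint). Makes
#: the baseline flags genuine confounders: they shift both insomnia odds and
#: outcome rates.
DEFAULT_OUTCOME_COVARIATE_EFFECTS: dict[str, float] = {
    "anxiety": 1.6,
    "depression": 1.4,
    "obesity": 1.2,
}


def _prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")
    return float(value)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims generator.

    The defaults are the study conditions the generator emulates: cohort mix,
    baseline prevalences, outcome rates and confounding strengths shaped like
    the motivating claims study, with an enrollment-span distribution long
    enough to host a 1-year look-back plus an observation window.
    """

    n_patients: int = 2000
    seed: int = 0
    baseline_covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS)
    )
    insomnia_marginal: float = 0.143
    treatment_probability_given_insomnia: float = 0.25
    outcome_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BASE_RATES)
    )
    outcome_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS)
    )
    outcome_covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COVARIATE_EFFECTS)
    )
    duplicate_claim_probability: float = 0.05
    outlier_patient_probability: float = 0.001
    enrollment_mean_days: float = 1200.0
    enrollment_shape: float = 4.0
    min_enrollment_days: int = 500
    data_end: int = 1638
    lookback_days: int = 365
    mean_age: float = 48.0
    sd_age: float = 15.1
    female_fraction: float = 0.58
    #: Mean number of follow-up insomnia diagnosis codes per insomniac
    #: (Poisson); each lands 30-170 days after the previous one, so most
    #: chain the rolling observation window onward.
    insomnia_extra_dx_mean: float = 0.8
    #: Upper bound (days) on how long after full look-back coverage the
    #: first insomnia diagnosis lands. With the default, insomniacs also
    #: contribute a pre-diagnosis control window (patients in both cohorts);
    #: set to 1 to make cohort membership disjoint.
    insomnia_dx_delay_max_days: int = 200
    #: Optional unmeasured confounder: log-odds shift on insomnia and rate
    #: multiplier on outcomes for a hidden Bernoulli(0.2) flag. Off (0, 1)
    #: by default so exchangeability holds by construction.
    unmeasured_confounder_logodds: float = 0.0
    unmeasured_confounder_rate_effect: float = 1.0

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        _prob("insomnia_marginal", self.insomnia_marginal)
        _prob(
            "treatment_probability_given_insomnia",
            self.treatment_probability_given_insomnia,
        )
        _prob("duplicate_claim_probability", self.duplicate_claim_probability)
        _prob("outlier_patient_probability", self.outlier_patient_probability)
        _prob("female_fraction", self.female_fraction)
        for name, p in self.baseline_covariate_prevalences.items():
            _prob(f"baseline_covariate_prevalences[{name}]", p)
        for name, r in self.outcome_base_rates.items():
            if r < 0:
                raise ConfigError(f"outcome_base_rates[{name}] must be >= 0, got {r}")
        for name, r in self.outcome_effects.items():
            if r < 0:
                raise ConfigError(f"outcome_effects[{name}] must be >= 0, got {r}")
        if self.enrollment_mean_days <= self.lookback_days:
            raise ConfigError(
                "enrollment_mean_days must exceed lookback_days "
                f"({self.enrollment_mean_days} <= {self.lookback_days})"
            )
        if self.min_enrollment_days <= self.lookback_days:
            raise ConfigError(
                "min_enrollment_days must exceed lookback_days "
                f"({self.min_enrollment_days} <= {self.lookback_days})"
            )
        if self.data_end <= self.min_enrollment_days:
            raise ConfigError("data_end must exceed min_enrollment_days")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-endpoint truth implied by a :class:`SimulationConfig`.

    ``ate_per_100py`` is the population-average additive effect of latent
    insomnia on post-onset event rates, on the 100 patient-year scale;
    ``rate_*`` are the corresponding counterfactual population-average rates
    per 100 patient-years.
    """

    rate_ratio: dict[str, float]
    rate_non_insomnia_per_100py: dict[str, float]
    rate_insomnia_per_100py: dict[str, float]
    ate_per_100py: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "GroundTruth":
        # E[prod_j c_j^{x_j}] for independent Bernoulli flags
        mult = 1.0
        for cov, c in config.outcome_covariate_effects.items():
            p = config.baseline_covariate_prevalences.get(cov, 0.0)
            mult *= 1.0 - p + p * c
        rr, r0, r1, ate = {}, {}, {}, {}
        for name, base in config.outcome_base_rates.items():
            effect = config.outcome_effects.get(name, 1.0)
            rr[name] = effect
            r0[name] = base * mult * 100.0
            r1[name] = base * effect * mult * 100.0
            ate[name] = base * (effect - 1.0) * mult * 100.0
        return cls(rr, r0, r1, ate)


def _insomnia_intercept(config: SimulationConfig) -> float:
    """Intercept making the marginal insomnia probability approximately hit
    the configured target given the covariate log-odds shifts."""
    adj = sum(
        beta * config.baseline_covariate_prevalences.get(cov, 0.0)
        for cov, beta in config.confounder_effects.items()
    )
    adj += config.unmeasured_confounder_logodds * 0.2
    return float(logit(config.insomnia_marginal)) - adj


def generate_population(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a synthetic claims population plus its analytic ground truth.

    Deterministic: the same config (including seed) yields an identical
    population, and hence byte-identical files from :func:`write_claims`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    code_sets = build_code_sets()
    cov_names = list(config.baseline_covariate_prevalences)
    # representative emitted code per set = lexicographically first prefix
    cov_codes = {name: min(code_sets[name].prefixes) for name in cov_names}
    outcome_codes = {
        name: min(code_sets[name].prefixes) for name in config.outcome_base_rates
    }
    insomnia_code = "G4700"
    disorientation_code = min(code_sets["disorientation"].prefixes)

    n = config.n_patients
    prev = np.array([config.baseline_covariate_prevalences[c] for c in cov_names])
    betas = np.array(
        [config.confounder_effects.get(c, 0.0) for c in cov_names]
    )
    flags = rng.random((n, len(cov_names))) < prev
    hidden = rng.random(n) < 0.2
    eta = (
        _insomnia_intercept(config)
        + flags @ betas
        + config.unmeasured_confounder_logodds * hidden
    )
    insomnia = rng.random(n) < expit(eta)
    treated = insomnia & (
        rng.random(n) < config.treatment_probability_given_insomnia
    )

    sex = np.where(rng.random(n) < config.female_fraction, FEMALE, MALE)
    ages = np.clip(rng.normal(config.mean_age, config.sd_age, n), 18, 90)
    # age is computed downstream from birth_year at index (~years 2016-2020)
    birth_years = 2016 - np.round(ages).astype(int)

    scale = config.enrollment_mean_days / config.enrollment_shape
    lengths = np.clip(
        rng.gamma(config.enrollment_shape, scale, n),
        config.min_enrollment_days,
        config.data_end,
    ).astype(int)
    starts = rng.integers(0, config.data_end - lengths + 1)
    ends = starts + lengths

    out_names = list(config.outcome_base_rates)
    base_rates = np.array([config.outcome_base_rates[o] for o in out_names])
    effects = np.array([config.outcome_effects.get(o, 1.0) for o in out_names])
    cov_mult = np.ones(n)
    for cov, c in config.outcome_covariate_effects.items():
        if cov in cov_names:
            cov_mult *= np.where(flags[:, cov_names.index(cov)], c, 1.0)
    cov_mult *= np.where(
        hidden, config.unmeasured_confounder_rate_effect, 1.0
    )
    # per-patient, per-endpoint yearly base rate; the insomnia rate ratio
    # applies from the first insomnia diagnosis onward (the planted burden
    # is post-onset, matching what the observation windows measure)
    lam0 = base_rates[None, :] * cov_mult[:, None]

    population: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:06d}"
        start, end = int(starts[i]), int(ends[i])
        events: list[ClaimEvent] = []

        # index date the cohort builders will find: diagnosis date for
        # insomniacs, first day with full look-back coverage for controls
        if insomnia[i]:
            slack = max(end - 1 - (start + config.lookback_days), 1)
            dx_day = start + config.lookback_days + int(
                rng.integers(0, min(slack, config.insomnia_dx_delay_max_days))
            )
            dx_day = min(dx_day, end - 1)
            index = dx_day
            events.append(ClaimEvent(pid, dx_day, DIAGNOSIS, insomnia_code))
            day = dx_day
            for _ in range(rng.poisson(config.insomnia_extra_dx_mean)):
                day += int(rng.integers(30, 171))
                if day >= end:
                    break
                events.append(ClaimEvent(pid, day, DIAGNOSIS, insomnia_code))
            if treated[i]:
                rx_day = dx_day + int(rng.integers(10, 121))
                if rx_day < end:
                    events.append(
                        ClaimEvent(pid, rx_day, PRESCRIPTION, "z_drug")
                    )
        else:
            index = start + config.lookback_days

        # look-back comorbidity codes for every active baseline flag
        lb_start = max(start, index - config.lookback_days)
        for j, active in enumerate(flags[i]):
            if active and lb_start < index:
                day = int(rng.integers(lb_start, index))
                events.append(ClaimEvent(pid, day, DIAGNOSIS, cov_codes[cov_names[j]]))

        # outcome events: memoryless process, rate stepped up at insomnia
        # onset (the diagnosis day) for insomniacs
        onset = dx_day if insomnia[i] else end
        spans = [(start, onset, 1.0), (onset, end, None)]
        for k, oname in enumerate(out_names):
            for lo, hi, factor in spans:
                if hi <= lo:
                    continue
                rate = lam0[i, k] * (effects[k] if factor is None else factor)
                n_events = rng.poisson(rate * (hi - lo) / DAYS_PER_YEAR)
                for day in rng.integers(lo, hi, n_events):
                    events.append(
                        ClaimEvent(pid, int(day), DIAGNOSIS, outcome_codes[oname])
                    )

        # duplicate same-day claims (what the dedup rule removes)
        if config.duplicate_claim_probability > 0:
            dup_mask = (
                rng.random(len(events)) < config.duplicate_claim_probability
            )
            events.extend([e for e, d in zip(list(events), dup_mask) if d])

        # rare outlier patient: >50 disorientation repeats in the look-back
        if rng.random() < config.outlier_patient_probability and lb_start < index:
            span = min(index - lb_start, 60)
            for offset in range(min(55, span)):
                events.append(
                    ClaimEvent(
                        pid, index - 1 - offset, DIAGNOSIS, disorientation_code
                    )
                )
            # top up on one day if the look-back is too short for 55 distinct
            # days (still >50 after dedup only when span allows; by default
            # span is 60 so 55 distinct days are always available)

        population.append(
            PatientRecord(
                patient_id=pid,
                sex=str(sex[i]),
                birth_year=int(birth_years[i]),
                enroll_start=start,
                enroll_end=end,
                events=tuple(events),
            )
        )
    return population, GroundTruth.from_config(config)
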