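"""End-to-end orchestration: generate -> build cohorts -> analyze -> report.

One :class:`RunConfig` collects every constant of the study design. A run
produces, under one output directory:

* ``claims/`` — the synthetic claims tables plus ``ground_truth.json``
  (omitted when analyzing claims supplied by the caller);
* ``attrition.csv`` — patient-flow counts with rejection reasons, including
  the internal-consistency identity ``eligible_total = untreated + control``;
* ``baseline_table.csv`` — per-cohort look-back prevalences, age and sex;
* ``results.csv`` — one row per endpoint x subgroup: weighted cohort means,
  ATE with bootstrap CI, raw and BH-adjusted p-values, balance verdict;
* ``balance.csv`` — per-subgroup, per-covariate standardized differences;
* ``results.json`` — the full bundle, including a provenance block recording
  every design default in force.

Everything is deterministic under the master seed: per-stage seeds are
derived from it, and all outputs are written with stable ordering, so two
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .codes_io import FEMALE, PatientRecord, read_claims, write_claims
from .cohorts import (
    NON_INSOMNIA,
    SUBGROUPS,
    UNTREATED_INSOMNIA,
    PatientTreatment,
    StudyConfig,
    assign_subgroups,
    build_cohorts,
    extract_covariates,
)
from .endpoints import (
    PREVALENCE,
    DAYS_PER_YEAR,
    EndpointSpec,
    TruncationPlan,
    default_endpoints,
    unit_responses,
)
from .estimation import (
    SCORE_EPS,
    _design_matrix,
    fit_logistic_scores,
    iptw_weights,
)
from .exceptions import ConfigError, EstimationError
from .inference import (
    BalanceReport,
    BootstrapSpec,
    benjamini_hochberg,
    bootstrap_cohort_analysis,
    bootstrap_test,
    _sd_columns,
)
from .synthetic import GroundTruth, SimulationConfig, generate_population


@dataclass
class RunConfig:
    """All knobs of one study run (defaults = the shipped study design)."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    reference_days: float = 131.0
    n_boot: int = 512
    sd_threshold: float = 0.15
    alpha: float = 0.05
    #: Restrict the endpoint roster to these names (None = full default
    #: roster).
    endpoint_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name, value in (
            ("reference_days", self.reference_days),
            ("n_boot", self.n_boot),
            ("sd_threshold", self.sd_threshold),
            ("alpha", self.alpha),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Build a RunConfig from a YAML mapping of overrides.

        Top-level keys override RunConfig fields; a ``simulation`` mapping
        overrides :class:`SimulationConfig` fields; a ``study`` mapping
        overrides the scalar :class:`StudyConfig` fields.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"run config {path} must be a mapping")
        sim = SimulationConfig(**data.pop("simulation", {}))
        study_kwargs = data.pop("study", {})
        study = StudyConfig(**study_kwargs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run-config fields: {sorted(unknown)}")
        cfg = cls(simulation=sim, study=study, **data)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def derived_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        return {
            "generate": int(state[0] % (2**31)),
            "bootstrap": int(state[1] % (2**31)),
        }

    def provenance(self) -> dict:
        """Every design default in force, for the report bundle."""
        return {
            "seed": self.seed,
            "lookback_days": self.study.lookback_days,
            "gap_days": self.study.gap_days,
            "outlier_threshold": self.study.outlier_threshold,
            "min_age": self.study.min_age,
            "reference_days": self.reference_days,
            "n_boot": self.n_boot,
            "sd_threshold": self.sd_threshold,
            "alpha": self.alpha,
            "days_per_year": DAYS_PER_YEAR,
            "score_clip_eps": SCORE_EPS,
            "exclusion_sets": list(self.study.exclusion_sets),
            "baseline_covariates": list(self.study.baseline_covariates),
            "n_patients_simulated": self.simulation.n_patients,
        }


@dataclass
class StudyReport:
    """In-memory result bundle of one run."""

    attrition: dict[str, int]
    baseline: pd.DataFrame
    results: pd.DataFrame
    balance: dict[str, pd.DataFrame]
    plan: TruncationPlan
    ground_truth: GroundTruth | None
    provenance: dict
    skipped_subgroups: list[str]


def baseline_percentage(count: int, total: int) -> float:
    """Baseline-table percentage, printed to one decimal (e.g. 61.0)."""
    if total <= 0:
        raise EstimationError("baseline percentage needs a positive denominator")
    return round(100.0 * count / total, 1)


def _covariate_frame(
    treatments: Sequence[PatientTreatment],
    patients: Mapping[str, PatientRecord],
    config: StudyConfig,
) -> pd.DataFrame:
    """One row per patient-treatment: cohort, windows, covariates, subgroups."""
    rows = []
    for t in treatments:
        profile = extract_covariates(t, patients[t.patient_id], config)
        sub = assign_subgroups(profile)
        row = {
            "patient_id": t.patient_id,
            "cohort": t.cohort,
            "index_date": t.index_date,
            "window_end": t.window_end,
            "duration_days": t.duration_days,
            "age": profile.age_at_index,
            "sex_female": int(profile.sex == FEMALE),
        }
        row.update({name: int(v) for name, v in profile.flags.items()})
        row.update({f"subgroup_{k}": int(v) for k, v in sub.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _baseline_table(units: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-cohort demographics and look-back prevalences."""
    rows = []
    for cohort in (UNTREATED_INSOMNIA, NON_INSOMNIA):
        sub = units[units["cohort"] == cohort]
        n = len(sub)
        if n == 0:
            continue
        rows.append(
            {"cohort": cohort, "variable": "n", "count": n, "value": float(n)}
        )
        rows.append(
            {
                "cohort": cohort,
                "variable": "mean_age",
                "count": n,
                "value": round(float(sub["age"].mean()), 1),
            }
        )
        female = int(sub["sex_female"].sum())
        rows.append(
            {
                "cohort": cohort,
                "variable": "female_pct",
                "count": female,
                "value": baseline_percentage(female, n),
            }
        )
        for name in config.baseline_covariates:
            count = int(sub[name].sum())
            rows.append(
                {
                    "cohort": cohort,
                    "variable": name,
                    "count": count,
                    "value": baseline_percentage(count, n),
                }
            )
    return pd.DataFrame(rows)


def _endpoint_specs(config: RunConfig) -> list[EndpointSpec]:
    specs = default_endpoints(config.study.code_sets)
    if config.endpoint_names is not None:
        wanted = set(config.endpoint_names)
        unknown = wanted - {s.name for s in specs}
        if unknown:
            raise ConfigError(f"unknown endpoint names: {sorted(unknown)}")
        specs = [s for s in specs if s.name in wanted]
    return specs


def analyze_cohorts(
    treatments: Sequence[PatientTreatment],
    patients: Mapping[str, PatientRecord],
    config: RunConfig,
    boot_seed: int,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], TruncationPlan, pd.DataFrame, list[str]]:
    """Weighted endpoint analysis across all subgroups.

    Returns (results table, per-subgroup balance tables, truncation plan,
    unit covariate frame, skipped subgroups).
    """
    units = _covariate_frame(treatments, patients, config.study)
    plan = TruncationPlan.from_treatments(treatments, config.reference_days)
    specs = _endpoint_specs(config)

    # per-unit responses per endpoint, aligned with the rows of `units`
    n = len(units)
    Y = np.zeros((n, len(specs)))
    T = np.zeros((n, len(specs)))
    metrics = [s.metric for s in specs]
    prev_scale = [
        (DAYS_PER_YEAR / plan.reference_days) * 100.0 if s.metric == PREVALENCE else 100.0
        for s in specs
    ]
    for e, spec in enumerate(specs):
        responses = unit_responses(treatments, spec, patients, plan)
        Y[:, e] = [r.y for r in responses]
        T[:, e] = [r.t for r in responses]

    covariate_cols = ["age", "sex_female", *config.study.baseline_covariates]
    rows: list[dict] = []
    balance: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for si, subgroup in enumerate(SUBGROUPS):
        mask = units[f"subgroup_{subgroup}"].to_numpy(dtype=bool)
        exposed = (units["cohort"] == UNTREATED_INSOMNIA).to_numpy()[mask]
        if mask.sum() < 4 or exposed.all() or (~exposed).all():
            skipped.append(subgroup)
            continue
        X = units.loc[mask, covariate_cols]
        try:
            design, names, _ = _design_matrix(X, continuous=("age",))
            scores, _, _ = fit_logistic_scores(design, exposed)
        except EstimationError:
            skipped.append(subgroup)
            continue
        weights = iptw_weights(scores, exposed)
        point_sd = _sd_columns(design, weights, exposed)

        spec_boot = BootstrapSpec(n_boot=config.n_boot, seed=boot_seed + si)
        ate_boot, sd_boot = bootstrap_cohort_analysis(
            design, exposed, Y[mask], T[mask], metrics, prev_scale, spec_boot
        )
        p95 = np.nanpercentile(sd_boot, 95, axis=0)
        report = BalanceReport(
            covariates=names,
            point_sd=point_sd,
            p95_sd=p95,
            threshold=config.sd_threshold,
            n_boot=config.n_boot,
        )
        balance[subgroup] = report.to_frame()

        yb, tb, wb = Y[mask], T[mask], weights
        for e, spec in enumerate(specs):
            mu_u = _weighted_mu_safe(
                yb[exposed, e], tb[exposed, e], wb[exposed], metrics[e], prev_scale[e]
            )
            mu_v = _weighted_mu_safe(
                yb[~exposed, e], tb[~exposed, e], wb[~exposed], metrics[e], prev_scale[e]
            )
            point = mu_u - mu_v
            p_raw, ci_low, ci_high = bootstrap_test(point, ate_boot[:, e])
            rows.append(
                {
                    "endpoint": spec.name,
                    "metric": spec.metric,
                    "subgroup": subgroup,
                    "n_untreated": int(exposed.sum()),
                    "n_control": int((~exposed).sum()),
                    "mu_untreated": mu_u,
                    "mu_control": mu_v,
                    "ate": point,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "p_raw": p_raw,
                    "n_boot": config.n_boot,
                    "balanced": report.balanced,
                }
            )

    results = pd.DataFrame(rows)
    if not results.empty:
        results["p_adjusted"] = benjamini_hochberg(results["p_raw"].to_numpy())
    return results, balance, plan, units, skipped


def _weighted_mu_safe(y, t, w, metric, scale) -> float:
    if metric == PREVALENCE:
        return float((w @ y) / w.sum() * scale)
    denom = float(w @ t)
    if denom <= 0:
        raise EstimationError("zero weighted exposure in point estimate")
    return float((w @ y) / denom * 100.0)


def run_study(
    config: RunConfig,
    out_dir: str | Path,
    claims_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the whole pipeline and write the report bundle.

    With ``claims_dir`` the three claims tables are read from disk; otherwise
    a synthetic population is generated (and written) with a seed derived
    from the master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.derived_seeds()

    ground_truth: GroundTruth | None = None
    if claims_dir is None:
        sim = dataclasses.replace(config.simulation, seed=seeds["generate"])
        population, ground_truth = generate_population(sim)
        claims_out = out_dir / "claims"
        write_claims(population, claims_out)
        (claims_out / "ground_truth.json").write_text(
            json.dumps(ground_truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    else:
        claims_dir = Path(claims_dir)
        population = read_claims(
            claims_dir / "patients.csv",
            claims_dir / "diagnoses.csv",
            claims_dir / "prescriptions.csv",
            epoch=config.study.epoch,
        )

    patients = {p.patient_id: p for p in population}
    treatments, attrition = build_cohorts(population, config.study)
    if not treatments:
        raise EstimationError("no eligible patient-treatments in the population")

    results, balance, plan, units, skipped = analyze_cohorts(
        treatments, patients, config, seeds["bootstrap"]
    )
    baseline = _baseline_table(units, config.study)

    attrition_dict = dict(sorted(attrition.items()))
    _write_outputs(
        out_dir, attrition_dict, baseline, results, balance, plan, config,
        ground_truth, skipped, units,
    )
    return StudyReport(
        attrition=attrition_dict,
        baseline=baseline,
        results=results,
        balance=balance,
        plan=plan,
        ground_truth=ground_truth,
        provenance=config.provenance(),
        skipped_subgroups=skipped,
    )


def _write_outputs(
    out_dir: Path,
    attrition: dict[str, int],
    baseline: pd.DataFrame,
    results: pd.DataFrame,
    balance: dict[str, pd.DataFrame],
    plan: TruncationPlan,
    config: RunConfig,
    ground_truth: GroundTruth | None,
    skipped: list[str],
    units: pd.DataFrame,
) -> None:
    pd.DataFrame(
        {"step": list(attrition), "count": list(attrition.values())}
    ).to_csv(out_dir / "attrition.csv", index=False)
    baseline.to_csv(out_dir / "baseline_table.csv", index=False)
    results.to_csv(out_dir / "results.csv", index=False)
    balance_rows = []
    for subgroup in sorted(balance):
        df = balance[subgroup].copy()
        df.insert(0, "subgroup", subgroup)
        balance_rows.append(df)
    if balance_rows:
        pd.concat(balance_rows, ignore_index=True).to_csv(
            out_dir / "balance.csv", index=False
        )
    units.to_csv(out_dir / "patient_treatments.csv", index=False)

    bundle = {
        "attrition": attrition,
        "truncation": {
            "reference_days": plan.reference_days,
            "fractions": dict(sorted(plan.fractions.items())),
        },
        "baseline": baseline.to_dict(orient="records"),
        "results": results.to_dict(orient="records"),
        "balance": {k: v.to_dict(orient="records") for k, v in sorted(balance.items())},
        "skipped_subgroups": skipped,
        "provenance": config.provenance(),
    }
    if ground_truth is not None:
        bundle["ground_truth"] = ground_truth.to_dict()
    (out_dir / "results.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=float) + "\n"
    )
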