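"""Claims data model, ICD-10 code-set matching, and tabular claims I/O.

Claims arrive as three delimited tables (patients, diagnoses, prescriptions).
All dates are integer day indices relative to a dataset epoch; ISO dates in
input files are converted on read. Diagnosis codes are ICD-10 and are matched
by normalized prefix, so a set entry ``F510`` covers the whole F51.0 family
(F51.01, F51.02, ...) — the conventional "F51.0X" family semantics.
Prescriptions carry drug-class tokens (e.g. ``z_drug``) rather than NDC codes;
the insomnia-treatment class vocabulary is configurable.

One cleaning rule lives here: same-day duplicate claims (same patient, day,
kind and code) are collapsed to a single record, as claims submitted multiple
times produce literal repeats. The >50-repeats outlier rule operates on
patient-treatment look-back windows and therefore lives in
:mod:`claimscohort.cohorts`.

All intervals in the package are half-open ``[start, end)`` on the day grid.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import DataError, InvalidCodeError, SchemaError

#: Calendar date of day index 0. Input files may carry ISO dates, which are
#: converted to day offsets from this epoch on read.
EPOCH = _dt.date(2015, 10, 1)

DIAGNOSIS = "diagnosis"
PRESCRIPTION = "prescription"

FEMALE = "F"
MALE = "M"


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10 (or drug-class) code string.

    Uppercases, strips surrounding whitespace and removes dots, so the two
    common ICD-10 dialects ("F51.01" and "F5101") collapse to one spelling.
    Idempotent.

    Raises
    ------
    InvalidCodeError
        If ``raw`` is empty or blank.
    """
    if raw is None:
        raise InvalidCodeError("empty or blank code: None")
    out = str(raw).upper().replace(".", "").strip()
    if not out:
        raise InvalidCodeError(f"empty or blank code: {raw!r}")
    return out


@dataclass(frozen=True, slots=True)
class ClaimEvent:
    """One dated, coded record for one patient — the atomic input unit.

    ``date`` is an integer day index (days since :data:`EPOCH`); ``kind`` is
    ``"diagnosis"`` or ``"prescription"`` and determines the code namespace
    (ICD-10 vs drug-class token).
    """

    patient_id: str
    date: int
    kind: str
    code: str

    def __post_init__(self) -> None:
        if self.date < 0:
            raise DataError(f"negative event date {self.date} for {self.patient_id}")
        if not self.code:
            raise InvalidCodeError("empty event code")
        if self.kind not in (DIAGNOSIS, PRESCRIPTION):
            raise DataError(f"unknown event kind {self.kind!r}")


@dataclass(slots=True)
class PatientRecord:
    """One patient: demographics, enrollment span and date-sorted events.

    Enrollment is half-open ``[enroll_start, enroll_end)`` and governs
    eligibility; events outside enrollment are kept (they still disqualify,
    e.g. an old insomnia prescription).
    """

    patient_id: str
    sex: str
    birth_year: int
    enroll_start: int
    enroll_end: int
    events: tuple[ClaimEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise DataError(f"sex must be F or M, got {self.sex!r}")
        if not self.enroll_start < self.enroll_end:
            raise DataError(
                f"enroll_start {self.enroll_start} must precede enroll_end "
                f"{self.enroll_end} for {self.patient_id}"
            )
        self.events = tuple(sorted(self.events, key=lambda e: (e.date, e.kind, e.code)))

    def diagnoses(self) -> tuple[ClaimEvent, ...]:
        return tuple(e for e in self.events if e.kind == DIAGNOSIS)

    def prescriptions(self) -> tuple[ClaimEvent, ...]:
        return tuple(e for e in self.events if e.kind == PRESCRIPTION)


@dataclass(frozen=True)
class CodeSet:
    """A named set of normalized ICD-10 prefixes.

    A code belongs to the set iff some prefix is a string-prefix of the
    normalized code. Within one set no prefix may be a prefix of another,
    which rules out double counting.
    """

    name: str
    prefixes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prefixes", _validate_prefixes(self.name, self.prefixes)
        )


def _validate_prefixes(name: str, prefixes: Iterable[str]) -> frozenset[str]:
    norm = frozenset(normalize_code(p) for p in prefixes)
    if not norm:
        raise SchemaError(f"code set {name!r} is empty")
    for a in norm:
        for b in norm:
            if a != b and b.startswith(a):
                raise SchemaError(
                    f"code set {name!r}: prefix {a!r} is a prefix of {b!r}"
                )
    return norm


def matches(code_set: CodeSet, code: str) -> bool:
    """True iff some prefix in ``code_set`` is a string-prefix of ``code``.

    ``code`` must already be normalized (see :func:`normalize_code`).
    """
    return any(code.startswith(p) for p in code_set.prefixes)


def deduplicate_same_day(events: Sequence[ClaimEvent]) -> list[ClaimEvent]:
    """Collapse same-day duplicate claims.

    Keeps at most one event per ``(patient_id, date, kind, code)`` tuple,
    preserving the relative order of survivors. Idempotent.
    """
    seen: set[tuple[str, int, str, str]] = set()
    out: list[ClaimEvent] = []
    for e in events:
        key = (e.patient_id, e.date, e.kind, e.code)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# Default code-set configuration
# ---------------------------------------------------------------------------

#: Default ICD-10 prefix sets (written with dots for readability; normalized
#: on load). Every set is user-overridable through a YAML/JSON config.
DEFAULT_CODE_PREFIXES: dict[str, tuple[str, ...]] = {
    # cohort definition
    "insomnia_dx": ("F51.0", "G47.0", "G47.8", "G47.9"),
    "circadian": ("G47.2",),
    # daytime-impairment endpoints
    "fatigue": ("R53.82", "R53.83"),
    "somnolence": ("R40.0",),
    "disorientation": ("R41.0",),
    "dizziness": ("R42",),
    "sleep_paralysis": ("G47.53",),
    "complex_sleep_behaviors": ("G47.52",),
    "falls": ("W0", "W1"),
    "injury_poisoning": ("S", "T"),
    # baseline comorbidity roster (one flag each in the covariate profile)
    "alcohol_drug_abuse": tuple(f"F1{i}" for i in range(10)),
    "chronic_pain": ("G89.4", "R52"),
    "anxiety": ("F41",),
    "depression": ("F32", "F33"),
    "psychiatric_comorbidities": ("F2", "F3", "F4"),
    "ptsd": ("F43.1",),
    "schizophreniform": ("F20",),
    "arterial_hypertension": ("I10", "I11", "I12", "I13", "I15"),
    "cerebral_infarction": ("I63",),
    "diabetes": ("E08", "E09", "E10", "E11", "E13"),
    "heart_failure": ("I50",),
    "ischemic_heart_disease": ("I20", "I21", "I22", "I23", "I24", "I25"),
    "metabolic_syndrome": ("E88.81",),
    "obesity": ("E66",),
    "copd": ("J44",),
    "obstructive_sleep_apnea": ("G47.33",),
    "dementia": ("F01", "F02", "F03", "G30"),
    "neurodegenerative": ("G31",),
    "parkinsons": ("G20",),
    "rls": ("G25.81",),
    # study exclusions (pregnancy / palliative care / active malignancy)
    "pregnancy": ("Z34", "O"),
    "palliative_care": ("Z51.5",),
    "malignancy": ("C",),
    # Charlson-roster extras used only by the young-healthy subgroup screen
    "charlson_mi": ("I21", "I22", "I25.2"),
    "charlson_pvd": ("I70", "I71", "I73"),
    "charlson_cerebrovascular": ("I6", "G45"),
    "charlson_rheumatic": ("M05", "M06", "M32", "M33", "M34"),
    "charlson_peptic_ulcer": ("K25", "K26", "K27", "K28"),
    "charlson_liver_mild": ("B18", "K70", "K73", "K74"),
    "charlson_hemiplegia": ("G81", "G82"),
    "charlson_renal": ("N18", "N19"),
    "charlson_liver_severe": ("K72", "I85"),
    "charlson_metastatic": ("C77", "C78", "C79", "C80"),
    "charlson_aids": ("B20",),
}

#: Drug-class tokens counted as insomnia treatment (prescription namespace).
DEFAULT_TREATMENT_CLASSES: frozenset[str] = frozenset(
    {"benzodiazepine", "z_drug", "trazodone", "dora", "ramelteon",
     "tetracyclic", "tricyclic"}
)

#: Covariate-profile roster: baseline conditions flagged over the look-back.
BASELINE_COVARIATES: tuple[str, ...] = (
    "alcohol_drug_abuse", "chronic_pain", "anxiety", "depression",
    "psychiatric_comorbidities", "ptsd", "schizophreniform",
    "arterial_hypertension", "cerebral_infarction", "diabetes",
    "heart_failure", "ischemic_heart_disease", "metabolic_syndrome",
    "obesity", "copd", "obstructive_sleep_apnea", "dementia",
    "neurodegenerative", "parkinsons", "rls",
)

#: Chronic-condition roster used to screen the "young and otherwise healthy"
#: subgroup: any look-back diagnosis from these sets disqualifies.
CHARLSON_SETS: tuple[str, ...] = (
    "charlson_mi", "heart_failure", "charlson_pvd",
    "charlson_cerebrovascular", "dementia", "copd", "charlson_rheumatic",
    "charlson_peptic_ulcer", "charlson_liver_mild", "diabetes",
    "charlson_hemiplegia", "charlson_renal", "malignancy",
    "charlson_liver_severe", "charlson_metastatic", "charlson_aids",
)


def build_code_sets(
    prefixes: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, CodeSet]:
    """Build named :class:`CodeSet` objects, defaults merged with overrides."""
    merged: dict[str, Iterable[str]] = dict(DEFAULT_CODE_PREFIXES)
    if prefixes:
        merged.update(prefixes)
    return {
        name: CodeSet(name=name, prefixes=frozenset(pfx))
        for name, pfx in merged.items()
    }


def load_code_sets(path: str | Path) -> dict[str, CodeSet]:
    """Load code-set overrides from a YAML or JSON file and merge defaults.

    The file maps set names to lists of ICD-10 prefixes.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"code-set file {path} must map names to prefix lists")
    return build_code_sets(data)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ("patient_id", "sex", "birth_year", "enroll_start", "enroll_end")
DIAGNOSIS_COLUMNS = ("patient_id", "date", "icd10")
PRESCRIPTION_COLUMNS = ("patient_id", "date", "drug_class")


def to_day_index(value, epoch: _dt.date = EPOCH) -> int:
    """Convert an integer day index or ISO date string to a day index."""
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return int(value)
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return (_dt.date.fromisoformat(s) - epoch).days
    except ValueError as exc:
        raise DataError(f"unparseable date {value!r}") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], label: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{label} file is missing required column {col!r}")


def _parse_dates(series: pd.Series, label: str, epoch: _dt.date) -> list[int]:
    out = []
    for pos, value in enumerate(series):
        try:
            out.append(to_day_index(value, epoch))
        except DataError as exc:
            # +2: one for the header row, one for 1-based line numbers
            raise DataError(f"{label} file line {pos + 2}: {exc}") from exc
    return out


def read_claims(
    patients_path: str | Path,
    diagnoses_path: str | Path,
    prescriptions_path: str | Path,
    epoch: _dt.date = EPOCH,
) -> list[PatientRecord]:
    """Read the three claims tables into :class:`PatientRecord` objects.

    Events are normalized, sorted by date and same-day deduplicated. Patients
    appearing only in the event files are ignored (no demographics, no
    eligibility).
    """
    pat = pd.read_csv(patients_path, dtype={"patient_id": str})
    dx = pd.read_csv(diagnoses_path, dtype={"patient_id": str})
    rx = pd.read_csv(prescriptions_path, dtype={"patient_id": str})
    _require_columns(pat, PATIENT_COLUMNS, "patients")
    _require_columns(dx, DIAGNOSIS_COLUMNS, "diagnoses")
    _require_columns(rx, PRESCRIPTION_COLUMNS, "prescriptions")

    events: dict[str, list[ClaimEvent]] = {pid: [] for pid in pat["patient_id"]}
    dx_dates = _parse_dates(dx["date"], "diagnoses", epoch)
    for pid, date, code in zip(dx["patient_id"], dx_dates, dx["icd10"]):
        if pid in events:
            events[pid].append(ClaimEvent(pid, date, DIAGNOSIS, normalize_code(code)))
    rx_dates = _parse_dates(rx["date"], "prescriptions", epoch)
    for pid, date, code in zip(rx["patient_id"], rx_dates, rx["drug_class"]):
        if pid in events:
            events[pid].append(
                ClaimEvent(pid, date, PRESCRIPTION, str(code).strip().lower())
            )

    records = []
    starts = _parse_dates(pat["enroll_start"], "patients", epoch)
    ends = _parse_dates(pat["enroll_end"], "patients", epoch)
    for row, start, end in zip(pat.itertuples(index=False), starts, ends):
        evts = sorted(events[row.patient_id], key=lambda e: (e.date, e.kind, e.code))
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                sex=str(row.sex).strip().upper(),
                birth_year=int(row.birth_year),
                enroll_start=start,
                enroll_end=end,
                events=tuple(deduplicate_same_day(evts)),
            )
        )
    return records


def write_claims(
    population: Sequence[PatientRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Write a population back to the three tabular files.

    Dates are written as integer day indices, so a read/write/read cycle is
    an identity on the in-memory population (events deduplicated on read; a
    population carrying same-day duplicates will legitimately shrink).
    """
    if not population:
        raise DataError("cannot write an empty population")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pat_rows, dx_rows, rx_rows = [], [], []
    for p in population:
        pat_rows.append((p.patient_id, p.sex, p.birth_year, p.enroll_start, p.enroll_end))
        for e in p.events:
            if e.kind == DIAGNOSIS:
                dx_rows.append((e.patient_id, e.date, e.code))
            else:
                rx_rows.append((e.patient_id, e.date, e.code))
    paths = {
        "patients": out_dir / "patients.csv",
        "diagnoses": out_dir / "diagnoses.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }
    pd.DataFrame(pat_rows, columns=list(PATIENT_COLUMNS)).to_csv(
        paths["patients"], index=False
    )
    pd.DataFrame(dx_rows, columns=list(DIAGNOSIS_COLUMNS)).to_csv(
        paths["diagnoses"], index=False
    )
    pd.DataFrame(rx_rows, columns=list(PRESCRIPTION_COLUMNS)).to_csv(
        paths["prescriptions"], index=False
    )
    return paths
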