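"""Shared fixtures: hand-built patients and small synthetic populations."""

from __future__ import annotations

import pytest

from claimscohort import PatientRecord, StudyConfig
from claimscohort.codes_io import DIAGNOSIS, PRESCRIPTION, ClaimEvent


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture
def make_patient():
    """Factory for hand-built patients.

    ``events`` entries are ``(date, kind, code)``; codes are taken verbatim
    (pass normalized ICD-10 or drug-class tokens).
    """

    def _make(
        patient_id="P1",
        sex="F",
        birth_year=1980,
        enroll_start=0,
        enroll_end=1000,
        events=(),
    ) -> PatientRecord:
        evts = tuple(
            ClaimEvent(patient_id, date, kind, code) for date, kind, code in events
        )
        return PatientRecord(
            patient_id=patient_id,
            sex=sex,
            birth_year=birth_year,
            enroll_start=enroll_start,
            enroll_end=enroll_end,
            events=evts,
        )

    return _make


@pytest.fixture
def dx():
    return lambda date, code: (date, DIAGNOSIS, code)


@pytest.fixture
def rx():
    return lambda date, code: (date, PRESCRIPTION, code)
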