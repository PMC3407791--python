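"""Shared fixtures: small hand-built extracts and checklists.

Everything is generated programmatically; AS_OF is the screening date all
hand-built records are phrased relative to.
"""

from __future__ import annotations

from datetime import date

import pytest

from prescreen import (
    Criterion,
    CodeMatchMode,
    Comparator,
    DiagnosisRecord,
    EligibilityChecklist,
    Encounter,
    LabBound,
    LabResult,
    Patient,
    TemporalWindow,
    WarehouseExtract,
)

AS_OF = date(2011, 6, 1)


def make_patient(pid: str, dob: date = date(1980, 3, 1), sex: str = "F") -> Patient:
    return Patient(patient_id=pid, name=f"pt {pid}", date_of_birth=dob, sex=sex)


def scheduled_visit(pid: str, eid: str, day: date | None = None,
                    clinic: str = "FM-CLINIC-1") -> Encounter:
    return Encounter(
        encounter_id=eid,
        patient_id=pid,
        encounter_type="scheduled",
        start_date=day or date(2011, 6, 8),
        clinic_id=clinic,
        physician_id="D001",
    )


@pytest.fixture
def fm_criteria() -> tuple[Criterion, ...]:
    """Age >= 18; primary diabetes codes; pregnancy-code exclusion within
    12 months; HbA1c strictly between 7 and 10."""
    return (
        Criterion(criterion_id="age", kind="demographic", attribute="age",
                  comparator=Comparator.GE, value=18),
        Criterion(criterion_id="t2dm", kind="diagnosis",
                  codes=("25000", "25002"), match_mode=CodeMatchMode.IS_ANY_OF,
                  primary_only=True),
        Criterion(criterion_id="no_pregnancy", kind="diagnosis",
                  polarity="exclude", codes=("V220", "V221", "V222"),
                  window=TemporalWindow(kind="within_past_months", months=12)),
        Criterion(criterion_id="hba1c", kind="lab", test_code="HBA1C",
                  lower=LabBound(7.0, Comparator.GT),
                  upper=LabBound(10.0, Comparator.LT)),
    )


@pytest.fixture
def fm_checklist_fixture(fm_criteria) -> EligibilityChecklist:
    return EligibilityChecklist(
        trial_id="FM-TEST",
        criteria=fm_criteria,
        visit_window=TemporalWindow(
            kind="between_dates", start=AS_OF, end=date(2011, 6, 15)
        ),
    )


def build_combo_extracts(fm_criteria):
    """Patients realizing every achievable verdict vector for the four FM
    criteria: age and diagnosis criteria are closed-world (MET/NOT_MET),
    the lab criterion is open-world (MET/NOT_MET/UNKNOWN) — 24 vectors,
    split across two extracts of 12 patients each.

    Returns (extracts, expected) where expected maps patient_id to the
    intended {criterion_id: verdict} dict.
    """
    combos = [
        (a, d, p, l)
        for a in ("MET", "NOT_MET")
        for d in ("MET", "NOT_MET")
        for p in ("MET", "NOT_MET")
        for l in ("MET", "NOT_MET", "UNKNOWN")
    ]
    expected: dict[str, dict[str, str]] = {}
    groups: list[tuple[list, list, list, list]] = []
    for chunk_idx in range(2):
        patients, encounters, diagnoses, labs = [], [], [], []
        for j, combo in enumerate(combos[chunk_idx * 12:(chunk_idx + 1) * 12]):
            age_v, dx_v, preg_v, lab_v = combo
            pid = f"C{chunk_idx}{j:02d}"
            dob = date(1980, 3, 1) if age_v == "MET" else date(2000, 3, 1)
            patients.append(make_patient(pid, dob=dob))
            encounters.append(scheduled_visit(pid, f"V{pid}"))
            if dx_v == "MET":
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, icd9_code="25000", is_primary=True,
                    record_date=date(2011, 1, 10)))
            else:
                # non-primary record: must not satisfy a primary-only criterion
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, icd9_code="25000", is_primary=False,
                    record_date=date(2011, 1, 10)))
            if preg_v == "NOT_MET":  # exclusion trips: code inside window
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, icd9_code="V221", is_primary=False,
                    record_date=date(2011, 2, 1)))
            else:
                # stale code outside the 12-month window: must not trip
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, icd9_code="V221", is_primary=False,
                    record_date=date(2009, 1, 1)))
            if lab_v == "MET":
                labs.append(LabResult(pid, "HBA1C", 8.0, "%", date(2011, 5, 1)))
            elif lab_v == "NOT_MET":
                labs.append(LabResult(pid, "HBA1C", 11.0, "%", date(2011, 5, 1)))
            else:
                # a different analyte: no information about HbA1c
                labs.append(LabResult(pid, "GLU", 130.0, "mg/dL", date(2011, 5, 1)))
            expected[pid] = {
                "age": age_v, "t2dm": dx_v, "no_pregnancy": preg_v, "hba1c": lab_v,
            }
        groups.append((patients, encounters, diagnoses, labs))
    extracts = [
        WarehouseExtract(patients=p, encounters=e, diagnoses=d, labs=l,
                         extract_date=AS_OF)
        for p, e, d, l in groups
    ]
    return extracts, expected
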