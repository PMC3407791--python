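"""Independent brute-force eligibility evaluator.

A deliberately naive, exhaustive re-implementation of the screening
semantics, sharing only the data model with :mod:`prescreen.matcher` —
none of its evaluation code, not even the calendar arithmetic (month
windows are computed here with :mod:`calendar` clamping rather than
dateutil). Intended for small inputs (up to a few thousand patients) where
an O(patients x criteria x records) scan is instant; its whole purpose is
to disagree with the matcher if either is wrong.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date

from .criteria import Criterion, EligibilityChecklist
from .warehouse import WarehouseExtract

__all__ = ["OracleResult", "oracle_eligibility"]


@dataclass(frozen=True, slots=True)
class OracleResult:
    status: str  # ELIGIBLE | POSSIBLE | INELIGIBLE
    verdicts: dict


def _months_before(d: date, months: int) -> date:
    year, month = d.year, d.month - months
    while month <= 0:
        month += 12
        year -= 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def _completed_years(dob: date, on: date) -> int:
    years = on.year - dob.year
    if on.month < dob.month or (on.month == dob.month and on.day < dob.day):
        years -= 1
    return years


def _window_ok(c: Criterion, when: date, as_of: date) -> bool:
    if when > as_of:
        return False
    win = c.window
    if win is None:
        return True
    if win.kind == "within_past_months":
        return _months_before(as_of, win.months) <= when <= as_of
    if win.start is not None and when < win.start:
        return False
    if win.end is not None and when > win.end:
        return False
    return True


def _compare(op: str, left, right) -> bool:
    if op == "LT":
        return left < right
    if op == "LE":
        return left <= right
    if op == "GT":
        return left > right
    if op == "GE":
        return left >= right
    return left == right


def _code_ok(code: str, c: Criterion) -> bool:
    if c.match_mode.value == "IS_EXACTLY":
        return len(c.codes) == 1 and code == c.codes[0]
    return code in c.codes


def _verdict(c: Criterion, extract: WarehouseExtract, pid: str, as_of: date) -> str:
    if c.kind == "demographic":
        patient = next(p for p in extract.patients if p.patient_id == pid)
        if c.attribute == "age":
            observed = _completed_years(patient.date_of_birth, as_of)
            met = _compare(c.comparator.value, observed, c.value)
        else:
            met = _compare(
                c.comparator.value, patient.sex.upper(), str(c.value).upper()
            )
    elif c.kind == "diagnosis":
        met = False
        for row in extract.diagnoses:
            if row.patient_id != pid:
                continue
            if c.primary_only and not row.is_primary:
                continue
            if _code_ok(row.icd9_code, c) and _window_ok(c, row.record_date, as_of):
                met = True
    elif c.kind == "medication":
        met = False
        for row in extract.orders:
            if row.patient_id != pid:
                continue
            if _code_ok(row.drug_code, c) and _window_ok(c, row.record_date, as_of):
                met = True
    elif c.kind == "encounter":
        met = False
        for row in extract.encounters:
            if row.patient_id != pid or row.encounter_type != c.encounter_type:
                continue
            if c.clinic_ids is not None and row.clinic_id not in c.clinic_ids:
                continue
            if c.physician_ids is not None and row.physician_id not in c.physician_ids:
                continue
            if _window_ok(c, row.start_date, as_of):
                met = True
    else:  # lab — open world, most recent in-window value
        best = None
        for idx, row in enumerate(extract.labs):
            if row.patient_id != pid or row.test_code != c.test_code:
                continue
            if not _window_ok(c, row.record_date, as_of):
                continue
            if best is None or (row.record_date, idx) > (best[0].record_date, best[1]):
                best = (row, idx)
        if best is None:
            return "UNKNOWN"
        value = best[0].value
        met = True
        if c.lower is not None:
            met = met and _compare(c.lower.comparator.value, value, c.lower.value)
        if c.upper is not None:
            met = met and _compare(c.upper.comparator.value, value, c.upper.value)

    verdict = "MET" if met else "NOT_MET"
    if c.polarity == "exclude":
        verdict = "NOT_MET" if verdict == "MET" else "MET"
    return verdict


def _has_visit(extract: WarehouseExtract, pid: str,
               cl: EligibilityChecklist, as_of: date) -> bool:
    win = cl.visit_window
    for row in extract.encounters:
        if row.patient_id != pid or row.encounter_type != "scheduled":
            continue
        if win.kind == "within_past_months":
            lo, hi = _months_before(as_of, win.months), as_of
        else:
            lo, hi = win.start, win.end
        if lo is not None and row.start_date < lo:
            continue
        if hi is not None and row.start_date > hi:
            continue
        if cl.clinics is not None and row.clinic_id not in cl.clinics:
            continue
        if cl.physicians is not None and row.physician_id not in cl.physicians:
            continue
        return True
    return False


def oracle_eligibility(
    extract: WarehouseExtract, cl: EligibilityChecklist, as_of: date
) -> dict[str, OracleResult]:
    """Label every visit-passing patient by exhaustive re-evaluation."""
    out: dict[str, OracleResult] = {}
    for patient in extract.patients:
        pid = patient.patient_id
        if not _has_visit(extract, pid, cl, as_of):
            continue
        verdicts = {c.criterion_id: _verdict(c, extract, pid, as_of) for c in cl.criteria}
        values = list(verdicts.values())
        if "NOT_MET" in values:
            status = "INELIGIBLE"
        elif "UNKNOWN" in values:
            status = "POSSIBLE"
        else:
            status = "ELIGIBLE"
        out[pid] = OracleResult(status=status, verdicts=verdicts)
    return out
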