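"""Three-valued criteria evaluation, candidate scoring and population screening.

Warehouse data are incomplete by nature, so a criterion evaluates to one of
three verdicts: ``MET``, ``NOT_MET`` or ``UNKNOWN``. Two assumptions drive
the semantics:

* **Closed world for coded events** (diagnoses, medications, encounters):
  the billing record is treated as complete, so a matching record inside the
  window means the pattern is present and no record means it is absent —
  these criteria never return ``UNKNOWN``. This is how "not currently
  pregnant" is operationalized as "no pregnancy codes within the past 12
  months".
* **Open world for laboratory values**: a missing result carries no
  information, so a lab criterion with no in-window result is ``UNKNOWN``.
  When results exist, the bounds are applied to the most recent in-window
  value (screening asks about current disease state, e.g. HbA1c control).

Exclusion criteria flip ``MET`` and ``NOT_MET``; ``UNKNOWN`` is a fixed
point. A checklist combines its criteria by Kleene conjunction: any
``NOT_MET`` makes the patient ``INELIGIBLE``, all ``MET`` makes them
``ELIGIBLE``, and otherwise they are ``POSSIBLE`` — the stratum coordinators
follow up on by hand. The score is the fraction of criteria definitively
met, and candidates are ranked by (status, score desc, unknowns asc,
patient_id) so reports are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .criteria import (
    CodeMatchMode,
    Comparator,
    Criterion,
    EligibilityChecklist,
)
from .errors import ConfigurationError
from .warehouse import Encounter, PatientBundle, WarehouseExtract, bundle_for

__all__ = [
    "TriState",
    "CriterionResult",
    "ScreeningResult",
    "ScreeningReport",
    "age_on",
    "evaluate_criterion",
    "evaluate_checklist",
    "combine_verdicts",
    "screen_population",
    "write_report_csv",
    "write_report_json",
]


class TriState(str, Enum):
    MET = "MET"
    NOT_MET = "NOT_MET"
    UNKNOWN = "UNKNOWN"

    def negate(self) -> "TriState":
        if self is TriState.MET:
            return TriState.NOT_MET
        if self is TriState.NOT_MET:
            return TriState.MET
        return TriState.UNKNOWN


class OverallStatus(str, Enum):
    ELIGIBLE = "ELIGIBLE"
    POSSIBLE = "POSSIBLE"
    INELIGIBLE = "INELIGIBLE"


@dataclass(frozen=True, slots=True)
class CriterionResult:
    """Effective verdict for one criterion, with the records that drove it.

    ``verdict`` is post-polarity: for an exclusion criterion whose pattern
    was found, the verdict is ``NOT_MET``. ``evidence`` holds every record
    that contributed, so a coordinator can jump to source data.
    """

    criterion_id: str
    verdict: TriState
    evidence: tuple = ()
    reason: str = ""

    def evidence_refs(self) -> list[str]:
        refs = []
        for rec in self.evidence:
            kind = type(rec).__name__
            when = getattr(rec, "record_date", None) or getattr(rec, "start_date", None)
            what = (
                getattr(rec, "icd9_code", None)
                or getattr(rec, "test_code", None)
                or getattr(rec, "drug_code", None)
                or getattr(rec, "encounter_type", None)
                or ""
            )
            refs.append(f"{kind}:{what}@{when}")
        return refs


@dataclass(frozen=True, slots=True)
class ScreeningResult:
    patient_id: str
    name: str
    overall_status: OverallStatus
    score: float
    unknown_count: int
    criterion_results: tuple[CriterionResult, ...]
    next_visit: Encounter | None = None


@dataclass(frozen=True, slots=True)
class ScreeningReport:
    """Ranked candidate list for one trial at one as-of date.

    INELIGIBLE patients are omitted; ELIGIBLE candidates come first, then
    POSSIBLE, each block sorted by descending score, ascending unknown
    count, then patient_id. ``n_screened`` counts patients that passed the
    visit filter and were evaluated.
    """

    trial_id: str
    as_of: date
    results: tuple[ScreeningResult, ...]
    n_screened: int
    tool_version: str = _version


def age_on(date_of_birth: date, on: date) -> int:
    """Age in completed years on ``on`` (birthday comparison, no 365.25)."""
    years = on.year - date_of_birth.year
    if (on.month, on.day) < (date_of_birth.month, date_of_birth.day):
        years -= 1
    return years


def _in_window(d: date, criterion: Criterion, as_of: date) -> bool:
    # history never extends past as_of, with or without an explicit window
    if d > as_of:
        return False
    if criterion.window is None:
        return True
    return criterion.window.contains(d, as_of)


def _codes_match(record_code: str, criterion: Criterion) -> bool:
    if criterion.match_mode is CodeMatchMode.IS_EXACTLY:
        return len(criterion.codes) == 1 and record_code == criterion.codes[0]
    return record_code in criterion.codes


def _eval_demographic(c: Criterion, b: PatientBundle, as_of: date) -> CriterionResult:
    if c.attribute == "age":
        observed: object = age_on(b.patient.date_of_birth, as_of)
    elif c.attribute == "sex":
        observed = b.patient.sex.upper()
    else:
        raise ConfigurationError(
            f"criterion {c.criterion_id!r}: unknown demographic attribute "
            f"{c.attribute!r}"
        )
    assert c.comparator is not None
    target = str(c.value).upper() if c.attribute == "sex" else c.value
    met = c.comparator.apply(observed, target)
    verdict = TriState.MET if met else TriState.NOT_MET
    return CriterionResult(
        c.criterion_id,
        verdict,
        reason=f"{c.attribute}={observed} {c.comparator.symbol} {target}: {met}",
    )


def _eval_diagnosis(c: Criterion, b: PatientBundle, as_of: date) -> CriterionResult:
    hits = tuple(
        d
        for d in b.diagnoses
        if _codes_match(d.icd9_code, c)
        and (not c.primary_only or d.is_primary)
        and _in_window(d.record_date, c, as_of)
    )
    if hits:
        return CriterionResult(
            c.criterion_id,
            TriState.MET,
            evidence=hits,
            reason=f"{len(hits)} matching diagnosis record(s)",
        )
    return CriterionResult(
        c.criterion_id, TriState.NOT_MET, reason="no matching diagnosis in window"
    )


def _eval_medication(c: Criterion, b: PatientBundle, as_of: date) -> CriterionResult:
    hits = tuple(
        o
        for o in b.orders
        if _codes_match(o.drug_code, c) and _in_window(o.record_date, c, as_of)
    )
    if hits:
        return CriterionResult(
            c.criterion_id,
            TriState.MET,
            evidence=hits,
            reason=f"{len(hits)} matching order(s)",
        )
    return CriterionResult(
        c.criterion_id, TriState.NOT_MET, reason="no matching order in window"
    )


def _eval_encounter(c: Criterion, b: PatientBundle, as_of: date) -> CriterionResult:
    hits = tuple(
        e
        for e in b.encounters
        if e.encounter_type == c.encounter_type
        and (c.clinic_ids is None or e.clinic_id in c.clinic_ids)
        and (c.physician_ids is None or e.physician_id in c.physician_ids)
        and _in_window(e.start_date, c, as_of)
    )
    if hits:
        return CriterionResult(
            c.criterion_id,
            TriState.MET,
            evidence=hits,
            reason=f"{len(hits)} matching encounter(s)",
        )
    return CriterionResult(
        c.criterion_id, TriState.NOT_MET, reason="no matching encounter in window"
    )


def _eval_lab(c: Criterion, b: PatientBundle, as_of: date) -> CriterionResult:
    assert c.test_code is not None
    in_window = [
        r
        for r in b.labs
        if r.test_code == c.test_code and _in_window(r.record_date, c, as_of)
    ]
    if not in_window:
        return CriterionResult(
            c.criterion_id,
            TriState.UNKNOWN,
            reason=f"no {c.test_code} result in window",
        )
    # most recent value; among same-day repeats the last-loaded row wins
    latest = max(
        range(len(in_window)), key=lambda i: (in_window[i].record_date, i)
    )
    result = in_window[latest]
    ok = (c.lower is None or c.lower.holds(result.value)) and (
        c.upper is None or c.upper.holds(result.value)
    )
    bounds = []
    if c.lower is not None:
        bounds.append(f"{c.lower.value} {_mirror(c.lower.comparator)} value")
    if c.upper is not None:
        bounds.append(f"value {c.upper.comparator.symbol} {c.upper.value}")
    return CriterionResult(
        c.criterion_id,
        TriState.MET if ok else TriState.NOT_MET,
        evidence=(result,),
        reason=(
            f"{c.test_code}={result.value} on {result.record_date}; "
            f"{' and '.join(bounds)}: {ok}"
        ),
    )


def _mirror(cmp: Comparator) -> str:
    return {"GT": "<", "GE": "<="}.get(cmp.value, cmp.symbol)


_EVALUATORS = {
    "demographic": _eval_demographic,
    "diagnosis": _eval_diagnosis,
    "medication": _eval_medication,
    "encounter": _eval_encounter,
    "lab": _eval_lab,
}


def evaluate_criterion(
    c: Criterion, b: PatientBundle, as_of: date
) -> CriterionResult:
    """Evaluate one criterion against one patient as of a screening date."""
    result = _EVALUATORS[c.kind](c, b, as_of)
    if c.polarity == "exclude":
        result = CriterionResult(
            result.criterion_id,
            result.verdict.negate(),
            evidence=result.evidence,
            reason=f"exclusion: {result.reason}",
        )
    return result


def combine_verdicts(verdicts: list[TriState]) -> OverallStatus:
    """Kleene conjunction over per-criterion verdicts."""
    if any(v is TriState.NOT_MET for v in verdicts):
        return OverallStatus.INELIGIBLE
    if all(v is TriState.MET for v in verdicts):
        return OverallStatus.ELIGIBLE
    return OverallStatus.POSSIBLE


def evaluate_checklist(
    cl: EligibilityChecklist,
    b: PatientBundle,
    as_of: date,
    next_visit: Encounter | None = None,
) -> ScreeningResult:
    """Evaluate every criterion and combine into a scored screening result."""
    results = tuple(evaluate_criterion(c, b, as_of) for c in cl.criteria)
    verdicts = [r.verdict for r in results]
    met = sum(v is TriState.MET for v in verdicts)
    unknown = sum(v is TriState.UNKNOWN for v in verdicts)
    return ScreeningResult(
        patient_id=b.patient.patient_id,
        name=b.patient.name,
        overall_status=combine_verdicts(verdicts),
        score=met / len(verdicts),
        unknown_count=unknown,
        criterion_results=results,
        next_visit=next_visit,
    )


def _qualifying_visits(
    b: PatientBundle, cl: EligibilityChecklist, as_of: date
) -> list[Encounter]:
    visits = [
        e
        for e in b.encounters
        if e.encounter_type == "scheduled"
        and cl.visit_window.contains(e.start_date, as_of)
        and (cl.clinics is None or e.clinic_id in cl.clinics)
        and (cl.physicians is None or e.physician_id in cl.physicians)
    ]
    visits.sort(key=lambda e: (e.start_date, e.encounter_id))
    return visits


def screen_population(
    extract: WarehouseExtract,
    cl: EligibilityChecklist,
    as_of: date,
    include_ineligible: bool = False,
) -> ScreeningReport:
    """Screen every patient with a qualifying scheduled visit.

    Patients with no scheduled encounter inside the checklist's visit
    window (or failing its clinic/physician filters) are not evaluated at
    all — the trial cannot approach a patient who is not coming in.
    ``include_ineligible`` keeps INELIGIBLE rows (useful for evaluation
    studies where the screened population is the denominator).
    """
    results: list[ScreeningResult] = []
    n_screened = 0
    for pid in sorted(extract.patient_ids()):
        bundle = bundle_for(extract, pid)
        visits = _qualifying_visits(bundle, cl, as_of)
        if not visits:
            continue
        n_screened += 1
        upcoming = [v for v in visits if v.start_date >= as_of]
        next_visit = upcoming[0] if upcoming else visits[0]
        result = evaluate_checklist(cl, bundle, as_of, next_visit=next_visit)
        if result.overall_status is OverallStatus.INELIGIBLE and not include_ineligible:
            continue
        results.append(result)
    order = {
        OverallStatus.ELIGIBLE: 0,
        OverallStatus.POSSIBLE: 1,
        OverallStatus.INELIGIBLE: 2,
    }
    results.sort(
        key=lambda r: (
            order[r.overall_status],
            -r.score,
            r.unknown_count,
            r.patient_id,
        )
    )
    return ScreeningReport(
        trial_id=cl.trial_id,
        as_of=as_of,
        results=tuple(results),
        n_screened=n_screened,
    )


# ---------------------------------------------------------------------------
# Report output


def report_frame(report: ScreeningReport) -> pd.DataFrame:
    criterion_ids = (
        [r.criterion_id for r in report.results[0].criterion_results]
        if report.results
        else []
    )
    rows = []
    for r in report.results:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "name": r.name,
            "overall_status": r.overall_status.value,
            "score": f"{r.score:.4f}",
            "unknown_count": r.unknown_count,
            "next_visit_date": (
                r.next_visit.start_date.isoformat() if r.next_visit else ""
            ),
            "clinic_id": (r.next_visit.clinic_id or "") if r.next_visit else "",
        }
        for cr in r.criterion_results:
            row[cr.criterion_id] = cr.verdict.value
        rows.append(row)
    columns = [
        "patient_id",
        "name",
        "overall_status",
        "score",
        "unknown_count",
        "next_visit_date",
        "clinic_id",
    ] + criterion_ids
    return pd.DataFrame(rows, columns=columns)


def write_report_csv(report: ScreeningReport, path: str | Path) -> None:
    report_frame(report).to_csv(path, index=False, lineterminator="\n")


def write_report_json(report: ScreeningReport, path: str | Path) -> None:
    doc = {
        "trial_id": report.trial_id,
        "as_of": report.as_of.isoformat(),
        "tool_version": report.tool_version,
        "n_screened": report.n_screened,
        "results": [
            {
                "patient_id": r.patient_id,
                "name": r.name,
                "overall_status": r.overall_status.value,
                "score": round(r.score, 6),
                "unknown_count": r.unknown_count,
                "next_visit_date": (
                    r.next_visit.start_date.isoformat() if r.next_visit else None
                ),
                "criteria": [
                    {
                        "criterion_id": cr.criterion_id,
                        "verdict": cr.verdict.value,
                        "reason": cr.reason,
                        "evidence": cr.evidence_refs(),
                    }
                    for cr in r.criterion_results
                ],
            }
            for r in report.results
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
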