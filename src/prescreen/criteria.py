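"""Eligibility-criteria templates and checklist parsing.

Trial eligibility criteria are free text in protocols; to screen against a
warehouse they must be operationalized as instances of a small set of
recurring templates. Five kinds cover the checklists modeled here:

* ``demographic`` — an attribute compared to a value (``age >= 18``,
  ``sex == F``);
* ``diagnosis`` — presence of any/exactly one ICD-9 code from a set,
  optionally restricted to primary diagnoses and/or a temporal window;
* ``lab`` — the most recent result for a test falling between explicit
  bounds, each bound carrying its own strict/inclusive comparator
  (``7 < HbA1c < 10``);
* ``encounter`` — an encounter of a given type (e.g. an inpatient
  hospitalization) within a window, optionally filtered by clinic or
  physician;
* ``medication`` — an order for any of a set of drug codes within a window.

Each criterion has a polarity: ``include`` (the pattern must hold) or
``exclude`` (the pattern's presence disqualifies — e.g. pregnancy codes
within the past 12 months standing in for "not currently pregnant").

A checklist is a conjunctive, ordered set of criteria plus the visit window
that restricts screening to patients actually due in clinic. Checklists are
stored as versioned JSON documents; :func:`parse_checklist` and
:func:`serialize_checklist` round-trip them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path

from dateutil.relativedelta import relativedelta

from .errors import ChecklistSchemaError
from .warehouse import ENCOUNTER_TYPES, normalize_icd9

__all__ = [
    "Comparator",
    "CodeMatchMode",
    "TemporalWindow",
    "LabBound",
    "Criterion",
    "EligibilityChecklist",
    "ValidationIssue",
    "parse_checklist",
    "load_checklist",
    "serialize_checklist",
    "save_checklist",
    "validate_criterion",
    "validate_checklist",
    "bundled_checklist_path",
]

SCHEMA_VERSION = 1

CRITERION_KINDS = ("demographic", "diagnosis", "lab", "encounter", "medication")

#: Plausibility bounds for an age comparand; expert reviews of screening
#: tools repeatedly find unguarded age fields accepting values like 800.
AGE_RANGE = (0, 130)

#: Earliest plausible date in any criterion; the late bound is relative
#: (reference date + 5 years) since visit windows legitimately look forward.
DATE_FLOOR = date(1900, 1, 1)


class Comparator(str, Enum):
    """Strict and inclusive comparison operators, kept distinct on purpose:

    ambiguous phrasings ("more than" vs "at least") are a documented source
    of user error when setting laboratory bounds.
    """

    LT = "LT"
    LE = "LE"
    GT = "GT"
    GE = "GE"
    EQ = "EQ"

    def apply(self, left, right) -> bool:
        if self is Comparator.LT:
            return left < right
        if self is Comparator.LE:
            return left <= right
        if self is Comparator.GT:
            return left > right
        if self is Comparator.GE:
            return left >= right
        return left == right

    @property
    def symbol(self) -> str:
        return {"LT": "<", "LE": "<=", "GT": ">", "GE": ">=", "EQ": "=="}[self.value]


class CodeMatchMode(str, Enum):
    """How a record's code is matched against a criterion's code set.

    ``IS_ANY_OF`` (the default when omitted) matches membership.
    ``IS_EXACTLY`` requires the code set to be a single code equal to the
    record's; with several codes it can never match — the classic
    authoring mistake of leaving "is exactly" selected for a multi-code
    criterion, which :func:`validate_criterion` flags.
    """

    IS_EXACTLY = "IS_EXACTLY"
    IS_ANY_OF = "IS_ANY_OF"


@dataclass(frozen=True, slots=True)
class TemporalWindow:
    """A date window, inclusive at both ends.

    ``within_past_months`` resolves to ``[as_of - months, as_of]`` with
    calendar-month arithmetic clamped to end of month (12 months before
    2011-03-31 is 2010-03-31; one month before is 2011-02-28).
    ``between_dates`` is absolute; either end may be open.
    """

    kind: str  # "within_past_months" | "between_dates"
    months: int | None = None
    start: date | None = None
    end: date | None = None

    def resolve(self, as_of: date) -> tuple[date | None, date | None]:
        if self.kind == "within_past_months":
            assert self.months is not None
            return as_of - relativedelta(months=self.months), as_of
        return self.start, self.end

    def contains(self, d: date, as_of: date) -> bool:
        lo, hi = self.resolve(as_of)
        return (lo is None or d >= lo) and (hi is None or d <= hi)


@dataclass(frozen=True, slots=True)
class LabBound:
    value: float
    comparator: Comparator

    def holds(self, observed: float) -> bool:
        # bound comparators read "observed <cmp> bound": GT 7 means value > 7
        return self.comparator.apply(observed, self.value)


@dataclass(frozen=True, slots=True)
class Criterion:
    """One templated eligibility condition.

    Only the fields relevant to ``kind`` are populated; the rest stay at
    their defaults. Construction does not validate — use
    :func:`validate_criterion` (pure, returns issues) or parse through the
    schema, which raises on hard errors.
    """

    criterion_id: str
    kind: str
    polarity: str = "include"  # include | exclude
    window: TemporalWindow | None = None
    # demographic
    attribute: str | None = None
    comparator: Comparator | None = None
    value: object = None
    # diagnosis / medication
    codes: tuple[str, ...] = ()
    match_mode: CodeMatchMode = CodeMatchMode.IS_ANY_OF
    primary_only: bool = False
    # lab
    test_code: str | None = None
    lower: LabBound | None = None
    upper: LabBound | None = None
    # encounter
    encounter_type: str | None = None
    clinic_ids: frozenset[str] | None = None
    physician_ids: frozenset[str] | None = None


@dataclass(frozen=True, slots=True)
class EligibilityChecklist:
    """A trial's conjunctive criteria plus the clinic-visit filter."""

    trial_id: str
    criteria: tuple[Criterion, ...]
    visit_window: TemporalWindow
    clinics: frozenset[str] | None = None
    physicians: frozenset[str] | None = None


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    criterion_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.criterion_id}.{self.field}: {self.message}"


# ---------------------------------------------------------------------------
# Parsing


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ChecklistSchemaError(f"{where}: missing required field {key!r}")
    return doc[key]


def _parse_date_field(raw, where: str) -> date:
    try:
        return date.fromisoformat(str(raw))
    except ValueError:
        raise ChecklistSchemaError(f"{where}: invalid ISO date {raw!r}") from None


def _parse_comparator(raw, where: str) -> Comparator:
    try:
        return Comparator(str(raw).upper())
    except ValueError:
        raise ChecklistSchemaError(
            f"{where}: malformed comparator {raw!r} "
            f"(expected one of {', '.join(c.value for c in Comparator)})"
        ) from None


def _parse_window(doc: dict | None, where: str) -> TemporalWindow | None:
    if doc is None:
        return None
    kind = _require(doc, "kind", where)
    if kind == "within_past_months":
        months = _require(doc, "months", where)
        if not isinstance(months, int) or months < 1:
            raise ChecklistSchemaError(f"{where}.months: must be an integer >= 1")
        return TemporalWindow(kind=kind, months=months)
    if kind == "between_dates":
        start = doc.get("start")
        end = doc.get("end")
        win = TemporalWindow(
            kind=kind,
            start=_parse_date_field(start, f"{where}.start") if start else None,
            end=_parse_date_field(end, f"{where}.end") if end else None,
        )
        if win.start and win.end and win.end < win.start:
            raise ChecklistSchemaError(f"{where}: end before start")
        return win
    raise ChecklistSchemaError(f"{where}.kind: unknown window kind {kind!r}")


def _parse_bound(doc: dict | None, where: str) -> LabBound | None:
    if doc is None:
        return None
    value = _require(doc, "value", where)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ChecklistSchemaError(f"{where}.value: must be numeric")
    return LabBound(
        value=float(value),
        comparator=_parse_comparator(_require(doc, "comparator", where), where),
    )


def _parse_codes(doc: dict, where: str, icd9: bool) -> tuple[str, ...]:
    raw = _require(doc, "codes", where)
    if not isinstance(raw, list) or not raw:
        raise ChecklistSchemaError(f"{where}.codes: must be a non-empty list")
    if icd9:
        return tuple(normalize_icd9(str(c)) for c in raw)
    return tuple(str(c).strip().upper() for c in raw)


def _parse_criterion(doc: dict, index: int) -> Criterion:
    where = f"criteria[{index}]"
    cid = str(_require(doc, "id", where))
    kind = _require(doc, "kind", where)
    if kind not in CRITERION_KINDS:
        raise ChecklistSchemaError(
            f"{where}.kind: unknown criterion kind {kind!r} "
            f"(expected one of {', '.join(CRITERION_KINDS)})"
        )
    polarity = doc.get("polarity", "include")
    if polarity not in ("include", "exclude"):
        raise ChecklistSchemaError(f"{where}.polarity: must be include or exclude")
    window = _parse_window(doc.get("window"), f"{where}.window")
    base = Criterion(criterion_id=cid, kind=kind, polarity=polarity, window=window)

    if kind == "demographic":
        comparator = _parse_comparator(
            _require(doc, "comparator", where), f"{where}.comparator"
        )
        return replace(
            base,
            attribute=str(_require(doc, "attribute", where)).lower(),
            comparator=comparator,
            value=_require(doc, "value", where),
        )
    if kind in ("diagnosis", "medication"):
        mode = CodeMatchMode(doc.get("match_mode", CodeMatchMode.IS_ANY_OF.value))
        return replace(
            base,
            codes=_parse_codes(doc, where, icd9=(kind == "diagnosis")),
            match_mode=mode,
            primary_only=bool(doc.get("primary_only", False)),
        )
    if kind == "lab":
        lower = _parse_bound(doc.get("lower"), f"{where}.lower")
        upper = _parse_bound(doc.get("upper"), f"{where}.upper")
        if lower is None and upper is None:
            raise ChecklistSchemaError(f"{where}: lab criterion needs lower or upper")
        if lower is not None and upper is not None and lower.value >= upper.value:
            raise ChecklistSchemaError(
                f"{where}: bounds inverted (lower {lower.value} >= upper {upper.value})"
            )
        return replace(
            base,
            test_code=str(_require(doc, "test_code", where)).strip().upper(),
            lower=lower,
            upper=upper,
        )
    # encounter
    etype = _require(doc, "encounter_type", where)
    if etype not in ENCOUNTER_TYPES:
        raise ChecklistSchemaError(
            f"{where}.encounter_type: unknown type {etype!r}"
        )
    clinics = doc.get("clinics")
    physicians = doc.get("physicians")
    return replace(
        base,
        encounter_type=etype,
        clinic_ids=frozenset(map(str, clinics)) if clinics else None,
        physician_ids=frozenset(map(str, physicians)) if physicians else None,
    )


def parse_checklist(document: dict | str) -> EligibilityChecklist:
    """Parse and validate a checklist document (a dict or a JSON string)."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ChecklistSchemaError(f"invalid JSON: {exc}") from None
    if not isinstance(document, dict):
        raise ChecklistSchemaError("checklist document must be a JSON object")
    version = document.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ChecklistSchemaError(f"unsupported schema_version {version!r}")
    trial_id = str(_require(document, "trial_id", "checklist"))
    raw_criteria = _require(document, "criteria", "checklist")
    if not isinstance(raw_criteria, list) or not raw_criteria:
        raise ChecklistSchemaError("checklist.criteria: must be a non-empty list")
    criteria = tuple(_parse_criterion(c, i) for i, c in enumerate(raw_criteria))
    ids = [c.criterion_id for c in criteria]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ChecklistSchemaError(f"duplicate criterion id(s): {', '.join(dupes)}")
    visit_window = _parse_window(
        _require(document, "visit_window", "checklist"), "checklist.visit_window"
    )
    assert visit_window is not None
    clinics = document.get("clinics")
    physicians = document.get("physicians")
    return EligibilityChecklist(
        trial_id=trial_id,
        criteria=criteria,
        visit_window=visit_window,
        clinics=frozenset(map(str, clinics)) if clinics else None,
        physicians=frozenset(map(str, physicians)) if physicians else None,
    )


def load_checklist(path: str | Path) -> EligibilityChecklist:
    path = Path(path)
    if not path.exists():
        raise ChecklistSchemaError(f"checklist file {path} does not exist")
    return parse_checklist(path.read_text())


# ---------------------------------------------------------------------------
# Serialization (inverse of parsing, up to field order and defaults)


def _window_doc(win: TemporalWindow | None) -> dict | None:
    if win is None:
        return None
    if win.kind == "within_past_months":
        return {"kind": win.kind, "months": win.months}
    doc: dict = {"kind": win.kind}
    if win.start:
        doc["start"] = win.start.isoformat()
    if win.end:
        doc["end"] = win.end.isoformat()
    return doc


def _criterion_doc(c: Criterion) -> dict:
    doc: dict = {"id": c.criterion_id, "kind": c.kind, "polarity": c.polarity}
    if c.window is not None:
        doc["window"] = _window_doc(c.window)
    if c.kind == "demographic":
        doc.update(attribute=c.attribute, comparator=c.comparator.value, value=c.value)
    elif c.kind in ("diagnosis", "medication"):
        doc.update(codes=list(c.codes), match_mode=c.match_mode.value)
        if c.primary_only:
            doc["primary_only"] = True
    elif c.kind == "lab":
        doc["test_code"] = c.test_code
        if c.lower:
            doc["lower"] = {"value": c.lower.value, "comparator": c.lower.comparator.value}
        if c.upper:
            doc["upper"] = {"value": c.upper.value, "comparator": c.upper.comparator.value}
    else:
        doc["encounter_type"] = c.encounter_type
        if c.clinic_ids:
            doc["clinics"] = sorted(c.clinic_ids)
        if c.physician_ids:
            doc["physicians"] = sorted(c.physician_ids)
    return doc


def serialize_checklist(cl: EligibilityChecklist) -> dict:
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": cl.trial_id,
        "visit_window": _window_doc(cl.visit_window),
        "criteria": [_criterion_doc(c) for c in cl.criteria],
    }
    if cl.clinics:
        doc["clinics"] = sorted(cl.clinics)
    if cl.physicians:
        doc["physicians"] = sorted(cl.physicians)
    return doc


def save_checklist(cl: EligibilityChecklist, path: str | Path) -> None:
    Path(path).write_text(json.dumps(serialize_checklist(cl), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Validation (pure; returns issues instead of raising)


def _check_window(
    c: Criterion, win: TemporalWindow | None, issues: list[ValidationIssue],
    reference_date: date,
) -> None:
    if win is None:
        return
    ceiling = reference_date + relativedelta(years=5)
    for name, d in (("start", win.start), ("end", win.end)):
        if d is None:
            continue
        if d < DATE_FLOOR or d > ceiling:
            issues.append(
                ValidationIssue(
                    c.criterion_id,
                    f"window.{name}",
                    f"date {d} outside plausible range [{DATE_FLOOR}, {ceiling}]",
                )
            )
    if win.kind == "within_past_months" and (win.months is None or win.months < 1):
        issues.append(
            ValidationIssue(c.criterion_id, "window.months", "months must be >= 1")
        )


def validate_criterion(
    c: Criterion, reference_date: date | None = None
) -> list[ValidationIssue]:
    """Range/shape checks for a criterion; pure and deterministic.

    Returns an empty list iff the criterion passes every rule. The date
    ceiling is ``reference_date + 5 years`` (``date.today()`` when not
    given), so screening windows may extend into the near future.
    """
    reference_date = reference_date or date.today()
    issues: list[ValidationIssue] = []
    _check_window(c, c.window, issues, reference_date)

    if c.kind == "demographic":
        if c.attribute not in ("age", "sex"):
            issues.append(
                ValidationIssue(
                    c.criterion_id, "attribute", f"unknown attribute {c.attribute!r}"
                )
            )
        elif c.attribute == "age":
            if not isinstance(c.value, (int, float)) or isinstance(c.value, bool):
                issues.append(
                    ValidationIssue(c.criterion_id, "value", "age must be numeric")
                )
            elif not AGE_RANGE[0] <= c.value <= AGE_RANGE[1]:
                issues.append(
                    ValidationIssue(
                        c.criterion_id,
                        "value",
                        f"age {c.value} out of plausible range "
                        f"[{AGE_RANGE[0]}, {AGE_RANGE[1]}]",
                    )
                )
        elif c.attribute == "sex" and c.comparator is not Comparator.EQ:
            issues.append(
                ValidationIssue(
                    c.criterion_id, "comparator", "sex supports only EQ"
                )
            )
    elif c.kind in ("diagnosis", "medication"):
        if not c.codes:
            issues.append(ValidationIssue(c.criterion_id, "codes", "empty code set"))
        elif c.match_mode is CodeMatchMode.IS_EXACTLY and len(c.codes) > 1:
            issues.append(
                ValidationIssue(
                    c.criterion_id,
                    "match_mode",
                    "IS_EXACTLY with multiple codes can never match; "
                    "use IS_ANY_OF",
                )
            )
    elif c.kind == "lab":
        if not c.test_code:
            issues.append(ValidationIssue(c.criterion_id, "test_code", "missing"))
        if c.lower is None and c.upper is None:
            issues.append(
                ValidationIssue(c.criterion_id, "bounds", "no bound specified")
            )
        else:
            if c.lower is not None and c.lower.comparator not in (
                Comparator.GT,
                Comparator.GE,
            ):
                issues.append(
                    ValidationIssue(
                        c.criterion_id, "lower.comparator", "must be GT or GE"
                    )
                )
            if c.upper is not None and c.upper.comparator not in (
                Comparator.LT,
                Comparator.LE,
            ):
                issues.append(
                    ValidationIssue(
                        c.criterion_id, "upper.comparator", "must be LT or LE"
                    )
                )
            if (
                c.lower is not None
                and c.upper is not None
                and c.lower.value >= c.upper.value
            ):
                issues.append(
                    ValidationIssue(
                        c.criterion_id,
                        "bounds",
                        f"bounds inverted (lower {c.lower.value} >= "
                        f"upper {c.upper.value})",
                    )
                )
    elif c.kind == "encounter":
        if c.encounter_type not in ENCOUNTER_TYPES:
            issues.append(
                ValidationIssue(
                    c.criterion_id,
                    "encounter_type",
                    f"unknown encounter type {c.encounter_type!r}",
                )
            )
    return issues


def validate_checklist(
    cl: EligibilityChecklist, reference_date: date | None = None
) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    for c in cl.criteria:
        issues.extend(validate_criterion(c, reference_date))
    return issues


def bundled_checklist_path(name: str) -> Path:
    """Path to one of the bundled example checklists.

    Available: ``fm_trial_a``, ``fm_trial_b``, ``chf_trial_a``,
    ``chf_trial_b`` — a family-medicine diabetes pair and a chronic
    heart-failure pair mirroring typical pre-screening checklists.
    """
    path = Path(__file__).parent / "data" / "checklists" / f"{name}.json"
    if not path.exists():
        available = sorted(p.stem for p in path.parent.glob("*.json"))
        raise ChecklistSchemaError(
            f"no bundled checklist {name!r} (available: {', '.join(available)})"
        )
    return path
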