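"""Flat-file data-warehouse extract: record types, CSV I/O, integrity checks.

A hospital data warehouse integrates clinical, billing and administrative
data; for cohort discovery only a handful of discrete tables matter. The
extract modeled here is a five-table snapshot — patients, encounters, coded
diagnoses (ICD-9-CM), laboratory results and medication orders — written as
plain CSV so that a screening run needs no database connection.

Conventions
-----------
* All dates are ISO 8601 (``YYYY-MM-DD``); no other dialect is accepted.
* ICD-9 codes are stored dot-stripped and upper-cased, so ``428.1`` and
  ``4281`` compare equal; normalization is idempotent.
* CSV files are comma-separated UTF-8 with a header row (RFC 4180 quoting).
* ``extract_date`` comes from an optional ``manifest.json``; when absent it
  defaults to the latest date appearing anywhere in the extract.
* Clinical history rows (diagnoses, labs, orders, completed encounters) may
  not be dated after ``extract_date``; *scheduled* encounters may, since
  future appointments are exactly what pre-screening targets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import (
    ExtractFormatError,
    PatientNotFoundError,
    ReferentialIntegrityError,
)

__all__ = [
    "Patient",
    "Encounter",
    "DiagnosisRecord",
    "LabResult",
    "MedicationOrder",
    "PatientBundle",
    "WarehouseExtract",
    "normalize_icd9",
    "load_extract",
    "write_extract",
    "bundle_for",
]

ENCOUNTER_TYPES = ("inpatient", "outpatient", "scheduled")

_ICD9_NORMALIZED = re.compile(r"^(\d{3,5}|V\d{2,4}|E\d{3,4})$")


def normalize_icd9(code: str) -> str:
    """Normalize an ICD-9-CM code: strip whitespace and dots, upper-case.

    Raises :class:`ExtractFormatError` if the result does not match the
    ICD-9-CM grammar (3–5 digits, or a V/E prefix with its fractional part).
    Idempotent: normalizing a normalized code is the identity.
    """
    normalized = code.strip().upper().replace(".", "")
    if not _ICD9_NORMALIZED.match(normalized):
        raise ExtractFormatError(f"invalid ICD-9 code {code!r}")
    return normalized


@dataclass(frozen=True, slots=True)
class Patient:
    patient_id: str
    date_of_birth: date
    sex: str
    name: str = ""


@dataclass(frozen=True, slots=True)
class Encounter:
    encounter_id: str
    patient_id: str
    encounter_type: str  # inpatient | outpatient | scheduled
    start_date: date
    end_date: date | None = None
    clinic_id: str | None = None
    physician_id: str | None = None


@dataclass(frozen=True, slots=True)
class DiagnosisRecord:
    patient_id: str
    icd9_code: str  # normalized (dot-stripped, upper-case)
    record_date: date
    is_primary: bool = False
    encounter_id: str | None = None


@dataclass(frozen=True, slots=True)
class LabResult:
    patient_id: str
    test_code: str
    value: float
    units: str
    record_date: date


@dataclass(frozen=True, slots=True)
class MedicationOrder:
    patient_id: str
    drug_code: str
    drug_name: str
    record_date: date


@dataclass(frozen=True, slots=True)
class PatientBundle:
    """All records for a single patient, grouped by table."""

    patient: Patient
    encounters: tuple[Encounter, ...] = ()
    diagnoses: tuple[DiagnosisRecord, ...] = ()
    labs: tuple[LabResult, ...] = ()
    orders: tuple[MedicationOrder, ...] = ()


@dataclass
class WarehouseExtract:
    """A validated five-table extract plus its snapshot date."""

    patients: list[Patient]
    encounters: list[Encounter] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    orders: list[MedicationOrder] = field(default_factory=list)
    extract_date: date | None = None

    def __post_init__(self) -> None:
        if self.extract_date is None:
            self.extract_date = self._latest_date()
        self._validate()

    def _latest_date(self) -> date:
        dates: list[date] = [p.date_of_birth for p in self.patients]
        dates += [e.start_date for e in self.encounters]
        dates += [e.end_date for e in self.encounters if e.end_date]
        dates += [d.record_date for d in self.diagnoses]
        dates += [r.record_date for r in self.labs]
        dates += [o.record_date for o in self.orders]
        return max(dates) if dates else date.today()

    def _validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        known = set(ids)
        if len(known) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ExtractFormatError(f"duplicate patient_id(s): {', '.join(dupes)}")
        dob = {p.patient_id: p.date_of_birth for p in self.patients}
        for table, rows in (
            ("encounters", self.encounters),
            ("diagnoses", self.diagnoses),
            ("labs", self.labs),
            ("orders", self.orders),
        ):
            for i, row in enumerate(rows):
                if row.patient_id not in known:
                    raise ReferentialIntegrityError(
                        f"{table} row {i}: unknown patient {row.patient_id!r}"
                    )
                row_date = (
                    row.start_date if isinstance(row, Encounter) else row.record_date
                )
                if row_date < dob[row.patient_id]:
                    raise ExtractFormatError(
                        f"{table} row {i}: dated {row_date} before patient "
                        f"{row.patient_id!r} date of birth"
                    )
                assert self.extract_date is not None
                future_allowed = (
                    isinstance(row, Encounter) and row.encounter_type == "scheduled"
                )
                if not future_allowed and row_date > self.extract_date:
                    raise ExtractFormatError(
                        f"{table} row {i}: dated {row_date} after extract date "
                        f"{self.extract_date}"
                    )
        for i, enc in enumerate(self.encounters):
            if enc.end_date is not None and enc.end_date < enc.start_date:
                raise ExtractFormatError(
                    f"encounters row {i}: end_date {enc.end_date} before "
                    f"start_date {enc.start_date}"
                )
            if enc.encounter_type not in ENCOUNTER_TYPES:
                raise ExtractFormatError(
                    f"encounters row {i}: unknown encounter_type "
                    f"{enc.encounter_type!r}"
                )

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def iter_bundles(self) -> Iterator[PatientBundle]:
        for pid in self.patient_ids():
            yield bundle_for(self, pid)


# ---------------------------------------------------------------------------
# CSV I/O

_TABLE_COLUMNS = {
    "patients": ("patient_id", "name", "date_of_birth", "sex"),
    "encounters": (
        "encounter_id",
        "patient_id",
        "encounter_type",
        "start_date",
        "end_date",
        "clinic_id",
        "physician_id",
    ),
    "diagnoses": ("patient_id", "encounter_id", "icd9_code", "is_primary", "record_date"),
    "labs": ("patient_id", "test_code", "value", "units", "record_date"),
    "orders": ("patient_id", "drug_code", "drug_name", "record_date"),
}


def _read_table(directory: Path, name: str, required: bool) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        if required:
            raise ExtractFormatError(f"missing required file {path}")
        return pd.DataFrame(columns=list(_TABLE_COLUMNS[name]))
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[name] if c not in frame.columns]
    if missing:
        raise ExtractFormatError(
            f"{path.name}: missing column(s) {', '.join(missing)}"
        )
    return frame


def _parse_date(raw: str, where: str) -> date:
    try:
        return date.fromisoformat(raw.strip())
    except ValueError:
        raise ExtractFormatError(f"{where}: invalid ISO date {raw!r}") from None


def _opt(raw: str) -> str | None:
    raw = raw.strip()
    return raw or None


def _parse_bool(raw: str, where: str) -> bool:
    token = raw.strip().lower()
    if token in ("true", "1", "yes", "y", "t"):
        return True
    if token in ("false", "0", "no", "n", "f", ""):
        return False
    raise ExtractFormatError(f"{where}: invalid boolean {raw!r}")


def load_extract(directory: str | Path) -> WarehouseExtract:
    """Load and validate a five-table extract from ``directory``.

    ``patients.csv`` is required; missing child tables are treated as empty.
    An optional ``manifest.json`` may carry ``extract_date``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ExtractFormatError(f"extract directory {directory} does not exist")

    pats = _read_table(directory, "patients", required=True)
    patients = [
        Patient(
            patient_id=row.patient_id.strip(),
            name=row.name.strip(),
            date_of_birth=_parse_date(row.date_of_birth, f"patients.csv row {i}"),
            sex=row.sex.strip().upper(),
        )
        for i, row in enumerate(pats.itertuples(index=False))
    ]

    encs = _read_table(directory, "encounters", required=False)
    encounters = [
        Encounter(
            encounter_id=row.encounter_id.strip(),
            patient_id=row.patient_id.strip(),
            encounter_type=row.encounter_type.strip().lower(),
            start_date=_parse_date(row.start_date, f"encounters.csv row {i}"),
            end_date=(
                _parse_date(row.end_date, f"encounters.csv row {i}")
                if row.end_date.strip()
                else None
            ),
            clinic_id=_opt(row.clinic_id),
            physician_id=_opt(row.physician_id),
        )
        for i, row in enumerate(encs.itertuples(index=False))
    ]

    dxs = _read_table(directory, "diagnoses", required=False)
    diagnoses = [
        DiagnosisRecord(
            patient_id=row.patient_id.strip(),
            encounter_id=_opt(row.encounter_id),
            icd9_code=normalize_icd9(row.icd9_code),
            is_primary=_parse_bool(row.is_primary, f"diagnoses.csv row {i}"),
            record_date=_parse_date(row.record_date, f"diagnoses.csv row {i}"),
        )
        for i, row in enumerate(dxs.itertuples(index=False))
    ]

    labs_df = _read_table(directory, "labs", required=False)
    labs = []
    for i, row in enumerate(labs_df.itertuples(index=False)):
        try:
            value = float(row.value)
        except ValueError:
            raise ExtractFormatError(
                f"labs.csv row {i}: non-numeric value {row.value!r}"
            ) from None
        if value != value or value in (float("inf"), float("-inf")):
            raise ExtractFormatError(f"labs.csv row {i}: non-finite value")
        units = row.units.strip()
        if not units:
            raise ExtractFormatError(f"labs.csv row {i}: empty units")
        labs.append(
            LabResult(
                patient_id=row.patient_id.strip(),
                test_code=row.test_code.strip().upper(),
                value=value,
                units=units,
                record_date=_parse_date(row.record_date, f"labs.csv row {i}"),
            )
        )

    ords = _read_table(directory, "orders", required=False)
    orders = [
        MedicationOrder(
            patient_id=row.patient_id.strip(),
            drug_code=row.drug_code.strip().upper(),
            drug_name=row.drug_name.strip(),
            record_date=_parse_date(row.record_date, f"orders.csv row {i}"),
        )
        for i, row in enumerate(ords.itertuples(index=False))
    ]

    extract_date = None
    manifest = directory / "manifest.json"
    if manifest.exists():
        try:
            payload = json.loads(manifest.read_text())
        except json.JSONDecodeError as exc:
            raise ExtractFormatError(f"manifest.json: {exc}") from None
        if "extract_date" in payload:
            extract_date = _parse_date(str(payload["extract_date"]), "manifest.json")

    return WarehouseExtract(
        patients=patients,
        encounters=encounters,
        diagnoses=diagnoses,
        labs=labs,
        orders=orders,
        extract_date=extract_date,
    )


def write_extract(extract: WarehouseExtract, directory: str | Path) -> None:
    """Write the five CSV tables plus ``manifest.json`` to ``directory``.

    Output is deterministic: rows in stored order, ISO dates, booleans as
    ``true``/``false``, empty string for absent optional fields.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def frame(name: str, rows: list[dict]) -> None:
        df = pd.DataFrame(rows, columns=list(_TABLE_COLUMNS[name]))
        df.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")

    frame(
        "patients",
        [
            {
                "patient_id": p.patient_id,
                "name": p.name,
                "date_of_birth": p.date_of_birth.isoformat(),
                "sex": p.sex,
            }
            for p in extract.patients
        ],
    )
    frame(
        "encounters",
        [
            {
                "encounter_id": e.encounter_id,
                "patient_id": e.patient_id,
                "encounter_type": e.encounter_type,
                "start_date": e.start_date.isoformat(),
                "end_date": e.end_date.isoformat() if e.end_date else "",
                "clinic_id": e.clinic_id or "",
                "physician_id": e.physician_id or "",
            }
            for e in extract.encounters
        ],
    )
    frame(
        "diagnoses",
        [
            {
                "patient_id": d.patient_id,
                "encounter_id": d.encounter_id or "",
                "icd9_code": d.icd9_code,
                "is_primary": "true" if d.is_primary else "false",
                "record_date": d.record_date.isoformat(),
            }
            for d in extract.diagnoses
        ],
    )
    frame(
        "labs",
        [
            {
                "patient_id": r.patient_id,
                "test_code": r.test_code,
                "value": repr(r.value),
                "units": r.units,
                "record_date": r.record_date.isoformat(),
            }
            for r in extract.labs
        ],
    )
    frame(
        "orders",
        [
            {
                "patient_id": o.patient_id,
                "drug_code": o.drug_code,
                "drug_name": o.drug_name,
                "record_date": o.record_date.isoformat(),
            }
            for o in extract.orders
        ],
    )
    assert extract.extract_date is not None
    (directory / "manifest.json").write_text(
        json.dumps({"extract_date": extract.extract_date.isoformat()}, indent=2) + "\n"
    )


def bundle_for(extract: WarehouseExtract, patient_id: str) -> PatientBundle:
    """Group every record for ``patient_id`` into a :class:`PatientBundle`."""
    for p in extract.patients:
        if p.patient_id == patient_id:
            patient = p
            break
    else:
        raise PatientNotFoundError(f"unknown patient {patient_id!r}")
    return PatientBundle(
        patient=patient,
        encounters=tuple(e for e in extract.encounters if e.patient_id == patient_id),
        diagnoses=tuple(d for d in extract.diagnoses if d.patient_id == patient_id),
        labs=tuple(r for r in extract.labs if r.patient_id == patient_id),
        orders=tuple(o for o in extract.orders if o.patient_id == patient_id),
    )
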