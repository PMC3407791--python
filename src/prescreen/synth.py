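"""Synthetic warehouse extracts with known ground-truth eligibility.

The generator emulates the population a family-medicine diabetes trial
would pre-screen: adult primary-care patients with configurable prevalences
of type-2 diabetes, heart failure and (current) pregnancy, HbA1c values
with realistic missingness, hospitalizations in the past year, and
scheduled clinic visits inside a forward-looking window.

Crucially, eligibility labels are computed from the *latent* truth of each
simulated patient, not from the emitted records: when a lab value is
withheld (``lab_missingness``), the label still reflects the true value, so
missingness creates genuine UNKNOWNs for the matcher while the gold
standard stays complete — exactly the role the manual chart-review gold
standard plays for the tool in a validation study.

Determinism: a single ``numpy.random.default_rng(seed)`` (PCG64) stream is
drawn in a fixed per-patient order (age, birthday offset, sex, condition
indicators, HbA1c, lab emission, record-date offsets, visit, clinic,
physician, noise records), so a given config and seed always produce
byte-identical extract files.

The bundled ICD-9 code lists are illustrative toys for testing, not
clinical groupers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .criteria import (
    CodeMatchMode,
    Comparator,
    Criterion,
    EligibilityChecklist,
    LabBound,
    TemporalWindow,
)
from .errors import ConfigurationError
from .warehouse import (
    DiagnosisRecord,
    Encounter,
    LabResult,
    Patient,
    WarehouseExtract,
)

__all__ = [
    "DIABETES_CODES",
    "HEART_FAILURE_CODES",
    "HYPERTENSIVE_HF_CODES",
    "DIASTOLIC_HF_CODES",
    "PREGNANCY_CODES",
    "SynthConfig",
    "GoldLabels",
    "fm_checklist",
    "chf_checklist",
    "generate_population",
    "write_gold_labels",
]

# Toy code lists (non-clinical, for synthetic data and tests only).
DIABETES_CODES = ("25000", "25002", "25010", "25012")
HEART_FAILURE_CODES = ("4280", "4281", "4289")
HYPERTENSIVE_HF_CODES = ("40291", "40401", "40491")
DIASTOLIC_HF_CODES = ("42830", "42831", "42832", "42833")
PREGNANCY_CODES = ("V220", "V221", "V222")
NOISE_CODES = ("4019", "2720", "4659", "7295")  # hypertension, lipids, URI, pain


@dataclass
class SynthConfig:
    """Study conditions for the generated population.

    Defaults describe a mid-sized primary-care panel: diabetes prevalence
    well above community rates (the clinic the trial recruits from),
    roughly a third of HbA1c values absent from the warehouse, and most
    patients holding a scheduled visit inside the two-week screening
    window.
    """

    n_patients: int = 200
    seed: int = 0
    as_of: date = date(2011, 6, 1)
    condition_prevalences: dict = field(
        default_factory=lambda: {
            "type2_diabetes": 0.35,
            "heart_failure": 0.20,
            "pregnancy": 0.04,
        }
    )
    lab_missingness: float = 0.30
    hba1c_mean: float = 8.0
    hba1c_sd: float = 1.6
    hba1c_range: tuple[float, float] = (4.0, 15.0)
    age_mean: float = 52.0
    age_sd: float = 19.0
    age_range: tuple[int, int] = (5, 95)
    visit_probability: float = 0.85
    visit_days: int = 14
    clinics: tuple[str, ...] = ("FM-CLINIC-1", "FM-CLINIC-2", "CARD-CLINIC-1")
    physicians: tuple[str, ...] = ("D001", "D002", "D003", "D004")

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        probs = dict(self.condition_prevalences)
        probs["lab_missingness"] = self.lab_missingness
        probs["visit_probability"] = self.visit_probability
        for name, p in probs.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.visit_days < 1:
            raise ConfigurationError("visit_days must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        raw = json.loads(Path(path).read_text())
        if "as_of" in raw:
            raw["as_of"] = date.fromisoformat(raw["as_of"])
        for key in ("hba1c_range", "age_range", "clinics", "physicians"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)


@dataclass
class GoldLabels:
    """Latent-truth eligibility per visit-passing patient.

    ``status`` maps patient_id to ELIGIBLE/INELIGIBLE (latent truth is
    complete, so the gold standard is never POSSIBLE); ``per_criterion``
    maps patient_id to {criterion_id: bool} for the four checklist
    criteria.
    """

    status: dict[str, str]
    per_criterion: dict[str, dict[str, bool]]

    def eligible_ids(self) -> set[str]:
        return {pid for pid, s in self.status.items() if s == "ELIGIBLE"}


def fm_checklist(
    as_of: date, visit_days: int = 14, clinics: tuple[str, ...] | None = None
) -> EligibilityChecklist:
    """The family-medicine diabetes checklist the generator's labels target:

    age >= 18; primary type-2-diabetes diagnosis codes; no pregnancy codes
    within the past 12 months (exclusion); HbA1c strictly between 7 and 10.
    """
    return EligibilityChecklist(
        trial_id="FM-SYNTH",
        criteria=(
            Criterion(
                criterion_id="age",
                kind="demographic",
                attribute="age",
                comparator=Comparator.GE,
                value=18,
            ),
            Criterion(
                criterion_id="t2dm",
                kind="diagnosis",
                codes=DIABETES_CODES,
                match_mode=CodeMatchMode.IS_ANY_OF,
                primary_only=True,
            ),
            Criterion(
                criterion_id="no_pregnancy",
                kind="diagnosis",
                polarity="exclude",
                codes=PREGNANCY_CODES,
                window=TemporalWindow(kind="within_past_months", months=12),
            ),
            Criterion(
                criterion_id="hba1c",
                kind="lab",
                test_code="HBA1C",
                lower=LabBound(7.0, Comparator.GT),
                upper=LabBound(10.0, Comparator.LT),
            ),
        ),
        visit_window=TemporalWindow(
            kind="between_dates", start=as_of, end=as_of + timedelta(days=visit_days)
        ),
        clinics=frozenset(clinics) if clinics else None,
    )


def chf_checklist(as_of: date, visit_days: int = 14) -> EligibilityChecklist:
    """A heart-failure screening checklist: age >= 21, hospitalization
    within the past 12 months, hypertensive heart-failure codes."""
    return EligibilityChecklist(
        trial_id="CHF-SYNTH",
        criteria=(
            Criterion(
                criterion_id="age",
                kind="demographic",
                attribute="age",
                comparator=Comparator.GE,
                value=21,
            ),
            Criterion(
                criterion_id="hospitalization",
                kind="encounter",
                encounter_type="inpatient",
                window=TemporalWindow(kind="within_past_months", months=12),
            ),
            Criterion(
                criterion_id="htn_hf",
                kind="diagnosis",
                codes=HYPERTENSIVE_HF_CODES,
                match_mode=CodeMatchMode.IS_ANY_OF,
            ),
        ),
        visit_window=TemporalWindow(
            kind="between_dates", start=as_of, end=as_of + timedelta(days=visit_days)
        ),
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    # rejection sampling; deterministic given the stream position
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def generate_population(cfg: SynthConfig) -> tuple[WarehouseExtract, GoldLabels]:
    """Generate an extract plus latent-truth labels for the FM checklist.

    Labels cover exactly the patients holding a scheduled visit inside the
    screening window (others are never screened, so they have no label).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    as_of = cfg.as_of
    prev = cfg.condition_prevalences

    patients: list[Patient] = []
    encounters: list[Encounter] = []
    diagnoses: list[DiagnosisRecord] = []
    labs: list[LabResult] = []
    status: dict[str, str] = {}
    per_criterion: dict[str, dict[str, bool]] = {}
    enc_seq = 0

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        # fixed per-patient draw order — see module docstring
        age = int(round(_trunc_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range)))
        dob_offset = int(rng.integers(0, 365))
        dob = as_of - relativedelta(years=age) - timedelta(days=dob_offset)
        sex = "F" if rng.random() < 0.5 else "M"
        has_diabetes = rng.random() < prev.get("type2_diabetes", 0.0)
        u_preg = rng.random()
        is_pregnant = (
            sex == "F" and 15 <= age <= 50 and u_preg < prev.get("pregnancy", 0.0)
        )
        has_hf = rng.random() < prev.get("heart_failure", 0.0)
        hba1c = _trunc_normal(rng, cfg.hba1c_mean, cfg.hba1c_sd, *cfg.hba1c_range)
        lab_emitted = rng.random() >= cfg.lab_missingness
        lab_days_ago = int(rng.integers(1, 183))
        t2dm_days_ago = int(rng.integers(1, 720))
        t2dm_code = DIABETES_CODES[int(rng.integers(0, len(DIABETES_CODES)))]
        preg_days_ago = int(rng.integers(1, 330))
        preg_code = PREGNANCY_CODES[int(rng.integers(0, len(PREGNANCY_CODES)))]
        hf_days_ago = int(rng.integers(1, 330))
        hf_code = HEART_FAILURE_CODES[int(rng.integers(0, len(HEART_FAILURE_CODES)))]
        old_preg = rng.random() < 0.05
        old_preg_days = int(rng.integers(430, 900))
        has_visit = rng.random() < cfg.visit_probability
        visit_day = int(rng.integers(0, cfg.visit_days + 1))
        clinic = cfg.clinics[int(rng.integers(0, len(cfg.clinics)))]
        physician = cfg.physicians[int(rng.integers(0, len(cfg.physicians)))]
        extra_dx = rng.random() < 0.30
        extra_code = NOISE_CODES[int(rng.integers(0, len(NOISE_CODES)))]
        extra_days_ago = int(rng.integers(1, 720))

        patients.append(
            Patient(patient_id=pid, name=f"Patient {i}", date_of_birth=dob, sex=sex)
        )

        if has_diabetes:
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    icd9_code=t2dm_code,
                    is_primary=True,
                    record_date=as_of - timedelta(days=t2dm_days_ago),
                )
            )
        if is_pregnant:
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    icd9_code=preg_code,
                    is_primary=False,
                    record_date=as_of - timedelta(days=preg_days_ago),
                )
            )
        if old_preg and sex == "F" and not is_pregnant:
            # stale pregnancy code outside the 12-month window: must not
            # trip the exclusion criterion
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    icd9_code="V221",
                    is_primary=False,
                    record_date=as_of - timedelta(days=old_preg_days),
                )
            )
        if has_hf:
            enc_seq += 1
            eid = f"E{enc_seq:06d}"
            hf_date = as_of - timedelta(days=hf_days_ago)
            encounters.append(
                Encounter(
                    encounter_id=eid,
                    patient_id=pid,
                    encounter_type="inpatient",
                    start_date=hf_date,
                    end_date=hf_date + timedelta(days=3),
                )
            )
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    icd9_code=hf_code,
                    is_primary=True,
                    encounter_id=eid,
                    record_date=hf_date,
                )
            )
        if lab_emitted:
            labs.append(
                LabResult(
                    patient_id=pid,
                    test_code="HBA1C",
                    value=round(hba1c, 1),
                    units="%",
                    record_date=as_of - timedelta(days=lab_days_ago),
                )
            )
        if extra_dx:
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    icd9_code=extra_code,
                    is_primary=False,
                    record_date=as_of - timedelta(days=extra_days_ago),
                )
            )
        if has_visit:
            enc_seq += 1
            encounters.append(
                Encounter(
                    encounter_id=f"E{enc_seq:06d}",
                    patient_id=pid,
                    encounter_type="scheduled",
                    start_date=as_of + timedelta(days=visit_day),
                    clinic_id=clinic,
                    physician_id=physician,
                )
            )
            # latent truth; the emitted lab value is rounded to 0.1 so the
            # bound check uses the rounded value on both sides
            truth = {
                "age": age >= 18,
                "t2dm": has_diabetes,
                "no_pregnancy": not is_pregnant,
                "hba1c": 7.0 < round(hba1c, 1) < 10.0,
            }
            per_criterion[pid] = truth
            status[pid] = "ELIGIBLE" if all(truth.values()) else "INELIGIBLE"

    extract = WarehouseExtract(
        patients=patients,
        encounters=encounters,
        diagnoses=diagnoses,
        labs=labs,
        orders=[],
        extract_date=as_of,
    )
    return extract, GoldLabels(status=status, per_criterion=per_criterion)


def write_gold_labels(labels: GoldLabels, path: str | Path) -> None:
    criterion_ids = (
        sorted({k for v in labels.per_criterion.values() for k in v})
        if labels.per_criterion
        else []
    )
    rows = []
    for pid in sorted(labels.status):
        row: dict[str, object] = {"patient_id": pid, "status": labels.status[pid]}
        for cid in criterion_ids:
            row[cid] = "true" if labels.per_criterion[pid][cid] else "false"
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["patient_id", "status"] + criterion_ids)
    frame.to_csv(path, index=False, lineterminator="\n")
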