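"""Extract I/O: normalization, integrity checks, round-trips, bundling."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

import prescreen as ps
from prescreen.errors import (
    ExtractFormatError,
    PatientNotFoundError,
    ReferentialIntegrityError,
)

from conftest import AS_OF, make_patient


def write_csv(path, header, rows):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [("428.1", "4281"), ("4281", "4281"), ("v22.1", "V221"),
         ("E950.0", "E9500"), (" 250.00 ", "25000")],
    )
    def test_dot_stripping_and_case(self, raw, expected):
        assert ps.normalize_icd9(raw) == expected

    @given(st.from_regex(r"\d{3}(\.\d{1,2})?", fullmatch=True))
    @settings(max_examples=50, derandomize=True)
    def test_idempotent(self, raw):
        once = ps.normalize_icd9(raw)
        assert ps.normalize_icd9(once) == once

    @pytest.mark.parametrize("bad", ["", "42", "X123", "4.2", "123456"])
    def test_rejects_malformed_codes(self, bad):
        with pytest.raises(ExtractFormatError):
            ps.normalize_icd9(bad)


class TestLoadExtract:
    def test_patients_only_directory(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex",
                  ["P1,Ann,1980-03-01,F", "P2,Bob,1955-07-12,M"])
        extract = ps.load_extract(tmp_path)
        assert len(extract.patients) == 2
        assert extract.encounters == [] and extract.diagnoses == []

    def test_missing_patients_csv_is_fatal(self, tmp_path):
        with pytest.raises(ExtractFormatError, match="patients.csv"):
            ps.load_extract(tmp_path)

    def test_diagnosis_codes_normalized_on_load(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex", ["P1,Ann,1980-03-01,F"])
        write_csv(tmp_path / "diagnoses.csv",
                  "patient_id,encounter_id,icd9_code,is_primary,record_date",
                  ["P1,,428.1,true,2011-01-05"])
        extract = ps.load_extract(tmp_path)
        assert extract.diagnoses[0].icd9_code == "4281"

    def test_dangling_patient_reference_names_offender(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex", ["P1,Ann,1980-03-01,F"])
        write_csv(tmp_path / "labs.csv",
                  "patient_id,test_code,value,units,record_date",
                  ["P99,HBA1C,8.1,%,2011-01-05"])
        with pytest.raises(ReferentialIntegrityError, match="P99"):
            ps.load_extract(tmp_path)

    def test_manifest_extract_date_and_default(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex", ["P1,Ann,1980-03-01,F"])
        write_csv(tmp_path / "labs.csv",
                  "patient_id,test_code,value,units,record_date",
                  ["P1,HBA1C,8.1,%,2011-01-05"])
        assert ps.load_extract(tmp_path).extract_date == date(2011, 1, 5)
        (tmp_path / "manifest.json").write_text('{"extract_date": "2011-06-01"}')
        assert ps.load_extract(tmp_path).extract_date == date(2011, 6, 1)

    def test_history_after_extract_date_rejected(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex", ["P1,Ann,1980-03-01,F"])
        write_csv(tmp_path / "labs.csv",
                  "patient_id,test_code,value,units,record_date",
                  ["P1,HBA1C,8.1,%,2011-07-05"])
        (tmp_path / "manifest.json").write_text('{"extract_date": "2011-06-01"}')
        with pytest.raises(ExtractFormatError, match="after extract date"):
            ps.load_extract(tmp_path)

    def test_scheduled_encounters_may_be_in_the_future(self, tmp_path):
        write_csv(tmp_path / "patients.csv",
                  "patient_id,name,date_of_birth,sex", ["P1,Ann,1980-03-01,F"])
        write_csv(
            tmp_path / "encounters.csv",
            "encounter_id,patient_id,encounter_type,start_date,end_date,"
            "clinic_id,physician_id",
            ["E1,P1,scheduled,2011-06-10,,,"])
        (tmp_path / "manifest.json").write_text('{"extract_date": "2011-06-01"}')
        extract = ps.load_extract(tmp_path)
        assert extract.encounters[0].start_date == date(2011, 6, 10)


class TestRoundTripAndBundles:
    def test_write_load_write_round_trip_bytes(self, tmp_path):
        cfg = ps.SynthConfig(n_patients=30, seed=11)
        extract, _ = ps.generate_population(cfg)
        a, b = tmp_path / "a", tmp_path / "b"
        ps.write_extract(extract, a)
        ps.write_extract(ps.load_extract(a), b)
        for name in ("patients", "encounters", "diagnoses", "labs", "orders"):
            assert (a / f"{name}.csv").read_bytes() == (b / f"{name}.csv").read_bytes()

    def test_bundles_partition_child_tables(self):
        cfg = ps.SynthConfig(n_patients=40, seed=5)
        extract, _ = ps.generate_population(cfg)
        bundles = list(extract.iter_bundles())
        assert sum(len(b.diagnoses) for b in bundles) == len(extract.diagnoses)
        assert sum(len(b.labs) for b in bundles) == len(extract.labs)
        assert sum(len(b.encounters) for b in bundles) == len(extract.encounters)
        collected = sorted(
            (d.patient_id, d.icd9_code, d.record_date)
            for b in bundles for d in b.diagnoses
        )
        original = sorted(
            (d.patient_id, d.icd9_code, d.record_date) for d in extract.diagnoses
        )
        assert collected == original

    def test_bundle_for_unknown_patient(self):
        extract = ps.WarehouseExtract(patients=[make_patient("P1")],
                                      extract_date=AS_OF)
        with pytest.raises(PatientNotFoundError, match="P9"):
            ps.bundle_for(extract, "P9")

    def test_bundle_for_patient_without_records(self):
        extract = ps.WarehouseExtract(patients=[make_patient("P1")],
                                      extract_date=AS_OF)
        bundle = ps.bundle_for(extract, "P1")
        assert bundle.encounters == () and bundle.diagnoses == ()
        assert bundle.labs == () and bundle.orders == ()
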