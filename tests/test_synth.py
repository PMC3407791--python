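"""Synthetic population generator and brute-force oracle."""

from datetime import date

import pytest

import prescreen as ps
from prescreen.errors import ConfigurationError

from conftest import AS_OF, make_patient, scheduled_visit


class TestGeneratePopulation:
    def test_zero_patients(self):
        extract, labels = ps.generate_population(ps.SynthConfig(n_patients=0))
        assert extract.patients == [] and labels.status == {}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError, match="lab_missingness"):
            ps.generate_population(ps.SynthConfig(lab_missingness=1.5))

    def test_seeded_regeneration_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            extract, labels = ps.generate_population(
                ps.SynthConfig(n_patients=60, seed=123))
            ps.write_extract(extract, tmp_path / run)
            ps.write_gold_labels(labels, tmp_path / run / "gold_labels.csv")
        for name in ("patients.csv", "encounters.csv", "diagnoses.csv",
                     "labs.csv", "orders.csv", "gold_labels.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = ps.generate_population(ps.SynthConfig(n_patients=60, seed=1))
        b, _ = ps.generate_population(ps.SynthConfig(n_patients=60, seed=2))
        assert [p.date_of_birth for p in a.patients] != \
            [p.date_of_birth for p in b.patients]

    def test_labels_cover_exactly_visit_passing_patients(self):
        cfg = ps.SynthConfig(n_patients=80, seed=9)
        extract, labels = ps.generate_population(cfg)
        cl = ps.fm_checklist(cfg.as_of, cfg.visit_days)
        with_visit = {
            e.patient_id
            for e in extract.encounters
            if e.encounter_type == "scheduled"
            and cl.visit_window.contains(e.start_date, cfg.as_of)
        }
        assert set(labels.status) == with_visit

    def test_zero_missingness_engine_matches_latent_truth(self):
        cfg = ps.SynthConfig(n_patients=500, seed=31, lab_missingness=0.0)
        extract, labels = ps.generate_population(cfg)
        cl = ps.fm_checklist(cfg.as_of, cfg.visit_days)
        report = ps.screen_population(extract, cl, cfg.as_of,
                                      include_ineligible=True)
        predicted = {r.patient_id for r in report.results
                     if r.overall_status is ps.OverallStatus.ELIGIBLE}
        assert predicted == labels.eligible_ids()
        # totality: complete labs mean no UNKNOWN anywhere
        assert all(r.unknown_count == 0 for r in report.results)

    def test_possible_fraction_nondecreasing_in_missingness(self):
        fractions = []
        for missingness in (0.0, 0.3, 0.6):
            per_seed = []
            for seed in (1, 2, 3):
                cfg = ps.SynthConfig(n_patients=150, seed=seed,
                                     lab_missingness=missingness)
                extract, _ = ps.generate_population(cfg)
                cl = ps.fm_checklist(cfg.as_of, cfg.visit_days)
                report = ps.screen_population(extract, cl, cfg.as_of,
                                              include_ineligible=True)
                possible = sum(
                    r.overall_status is ps.OverallStatus.POSSIBLE
                    for r in report.results
                )
                per_seed.append(possible / max(report.n_screened, 1))
            fractions.append(sum(per_seed) / len(per_seed))
        assert fractions == sorted(fractions)

    def test_config_round_trip_from_json(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(
            '{"n_patients": 5, "seed": 2, "as_of": "2011-06-01", '
            '"lab_missingness": 0.1}'
        )
        cfg = ps.SynthConfig.from_json(path)
        assert cfg.n_patients == 5 and cfg.as_of == date(2011, 6, 1)
        with pytest.raises(ConfigurationError, match="bogus"):
            path.write_text('{"bogus": 1}')
            ps.SynthConfig.from_json(path)


class TestOracle:
    def test_trivial_always_true_demographic(self):
        extract = ps.WarehouseExtract(
            patients=[make_patient("P1")],
            encounters=[scheduled_visit("P1", "E1")],
            extract_date=AS_OF,
        )
        cl = ps.EligibilityChecklist(
            trial_id="T",
            criteria=(ps.Criterion(criterion_id="age", kind="demographic",
                                   attribute="age",
                                   comparator=ps.Comparator.GE, value=0),),
            visit_window=ps.TemporalWindow(kind="between_dates", start=AS_OF,
                                           end=date(2011, 6, 15)),
        )
        labels = ps.oracle_eligibility(extract, cl, AS_OF)
        assert labels["P1"].status == "ELIGIBLE"

    def test_missing_lab_gives_possible(self, fm_checklist_fixture):
        extract = ps.WarehouseExtract(
            patients=[make_patient("P1")],
            encounters=[scheduled_visit("P1", "E1")],
            diagnoses=[ps.DiagnosisRecord("P1", "25000", date(2011, 1, 10),
                                          is_primary=True)],
            extract_date=AS_OF,
        )
        labels = ps.oracle_eligibility(extract, fm_checklist_fixture, AS_OF)
        assert labels["P1"].status == "POSSIBLE"
        assert labels["P1"].verdicts["hba1c"] == "UNKNOWN"

    def test_matches_matcher_on_random_synthetic_population(self):
        cfg = ps.SynthConfig(n_patients=200, seed=77, lab_missingness=0.3)
        extract, _ = ps.generate_population(cfg)
        cl = ps.fm_checklist(cfg.as_of, cfg.visit_days)
        oracle = ps.oracle_eligibility(extract, cl, cfg.as_of)
        report = ps.screen_population(extract, cl, cfg.as_of,
                                      include_ineligible=True)
        engine = {r.patient_id: r for r in report.results}
        assert set(engine) == set(oracle)
        for pid, o in oracle.items():
            assert engine[pid].overall_status.value == o.status, pid
            engine_verdicts = {
                c.criterion_id: c.verdict.value
                for c in engine[pid].criterion_results
            }
            assert engine_verdicts == o.verdicts, pid
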