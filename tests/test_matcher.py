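"""Three-valued criterion evaluation, checklist combination and screening."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

import prescreen as ps
from prescreen.errors import ConfigurationError

from conftest import AS_OF, build_combo_extracts, make_patient, scheduled_visit


def bundle_of(patient, **kw):
    return ps.PatientBundle(patient=patient, **kw)


class TestEvaluateCriterion:
    def test_age_met_from_birthday_arithmetic(self):
        c = ps.Criterion(criterion_id="age", kind="demographic",
                         attribute="age", comparator=ps.Comparator.GE, value=21)
        b = bundle_of(make_patient("P1", dob=date(1985, 3, 1)))
        r = ps.evaluate_criterion(c, b, date(2011, 1, 15))
        assert r.verdict is ps.TriState.MET
        assert "25" in r.reason  # age 25: birthday not yet reached

    def test_age_boundary_is_completed_years(self):
        c = ps.Criterion(criterion_id="age", kind="demographic",
                         attribute="age", comparator=ps.Comparator.GE, value=26)
        b = bundle_of(make_patient("P1", dob=date(1985, 3, 1)))
        # day before the 26th birthday vs the birthday itself
        assert ps.evaluate_criterion(c, b, date(2011, 2, 28)).verdict \
            is ps.TriState.NOT_MET
        assert ps.evaluate_criterion(c, b, date(2011, 3, 1)).verdict \
            is ps.TriState.MET

    def test_unknown_demographic_attribute_raises(self):
        c = ps.Criterion(criterion_id="x", kind="demographic",
                         attribute="height", comparator=ps.Comparator.GE, value=2)
        with pytest.raises(ConfigurationError, match="height"):
            ps.evaluate_criterion(c, bundle_of(make_patient("P1")), AS_OF)

    def test_missing_lab_is_unknown(self, fm_criteria):
        hba1c = fm_criteria[3]
        r = ps.evaluate_criterion(hba1c, bundle_of(make_patient("P1")), AS_OF)
        assert r.verdict is ps.TriState.UNKNOWN
        assert r.evidence == ()

    def test_lab_uses_most_recent_in_window_value(self, fm_criteria):
        hba1c = fm_criteria[3]
        labs = (
            ps.LabResult("P1", "HBA1C", 12.0, "%", date(2011, 1, 1)),
            ps.LabResult("P1", "HBA1C", 8.0, "%", date(2011, 5, 1)),
        )
        r = ps.evaluate_criterion(hba1c, bundle_of(make_patient("P1"), labs=labs),
                                  AS_OF)
        assert r.verdict is ps.TriState.MET
        assert r.evidence[0].value == 8.0

    def test_lab_monotonicity_adding_older_result_never_flips(self, fm_criteria):
        hba1c = fm_criteria[3]
        recent = ps.LabResult("P1", "HBA1C", 8.0, "%", date(2011, 5, 1))
        older = ps.LabResult("P1", "HBA1C", 12.0, "%", date(2011, 1, 1))
        resolved = ps.evaluate_criterion(
            hba1c, bundle_of(make_patient("P1"), labs=(recent,)), AS_OF)
        with_older = ps.evaluate_criterion(
            hba1c, bundle_of(make_patient("P1"), labs=(older, recent)), AS_OF)
        assert with_older.verdict is resolved.verdict
        # and UNKNOWN resolves once any result exists
        unknown = ps.evaluate_criterion(
            hba1c, bundle_of(make_patient("P1")), AS_OF)
        assert unknown.verdict is ps.TriState.UNKNOWN
        assert ps.evaluate_criterion(
            hba1c, bundle_of(make_patient("P1"), labs=(older,)), AS_OF
        ).verdict is not ps.TriState.UNKNOWN

    def test_exclusion_flips_present_pattern_to_not_met(self, fm_criteria):
        pregnancy = fm_criteria[2]
        dx = (ps.DiagnosisRecord("P1", "V221", date(2010, 8, 1)),)  # 10 months ago
        r = ps.evaluate_criterion(pregnancy,
                                  bundle_of(make_patient("P1"), diagnoses=dx),
                                  AS_OF)
        assert r.verdict is ps.TriState.NOT_MET
        assert r.evidence == dx

    def test_stale_code_outside_window_does_not_trip_exclusion(self, fm_criteria):
        pregnancy = fm_criteria[2]
        dx = (ps.DiagnosisRecord("P1", "V221", date(2009, 1, 1)),)
        r = ps.evaluate_criterion(pregnancy,
                                  bundle_of(make_patient("P1"), diagnoses=dx),
                                  AS_OF)
        assert r.verdict is ps.TriState.MET

    def test_primary_only_diagnosis_with_evidence(self, fm_criteria):
        t2dm = fm_criteria[1]
        hit = ps.DiagnosisRecord("P1", "25000", date(2011, 1, 10), is_primary=True)
        miss = ps.DiagnosisRecord("P1", "25002", date(2011, 1, 10), is_primary=False)
        r = ps.evaluate_criterion(
            t2dm, bundle_of(make_patient("P1"), diagnoses=(miss, hit)), AS_OF)
        assert r.verdict is ps.TriState.MET
        assert r.evidence == (hit,)

    def test_is_exactly_matches_only_singleton_code_sets(self):
        single = ps.Criterion(criterion_id="dx", kind="diagnosis",
                              codes=("25000",),
                              match_mode=ps.CodeMatchMode.IS_EXACTLY)
        multi = ps.Criterion(criterion_id="dx", kind="diagnosis",
                             codes=("25000", "25002"),
                             match_mode=ps.CodeMatchMode.IS_EXACTLY)
        dx = (ps.DiagnosisRecord("P1", "25000", date(2011, 1, 10)),)
        b = bundle_of(make_patient("P1"), diagnoses=dx)
        assert ps.evaluate_criterion(single, b, AS_OF).verdict is ps.TriState.MET
        assert ps.evaluate_criterion(multi, b, AS_OF).verdict is ps.TriState.NOT_MET

    def test_medication_order_match(self):
        c = ps.Criterion(criterion_id="rx", kind="medication",
                         codes=("METF500", "METF1000"),
                         window=ps.TemporalWindow(kind="within_past_months",
                                                  months=12))
        orders = (ps.MedicationOrder("P1", "METF500", "Metformin",
                                     date(2011, 2, 1)),)
        r = ps.evaluate_criterion(c, bundle_of(make_patient("P1"), orders=orders),
                                  AS_OF)
        assert r.verdict is ps.TriState.MET

    def test_encounter_criterion_respects_window(self):
        c = ps.Criterion(criterion_id="hosp", kind="encounter",
                         encounter_type="inpatient",
                         window=ps.TemporalWindow(kind="within_past_months",
                                                  months=12))
        old = ps.Encounter("E1", "P1", "inpatient", date(2009, 1, 1))
        b = bundle_of(make_patient("P1"), encounters=(old,))
        assert ps.evaluate_criterion(c, b, AS_OF).verdict is ps.TriState.NOT_MET
        recent = ps.Encounter("E2", "P1", "inpatient", date(2011, 1, 1))
        b = bundle_of(make_patient("P1"), encounters=(old, recent))
        assert ps.evaluate_criterion(c, b, AS_OF).verdict is ps.TriState.MET


VERDICTS = [ps.TriState.MET, ps.TriState.NOT_MET, ps.TriState.UNKNOWN]


def kleene_min_oracle(verdicts):
    """Kleene AND as a minimum over the order NOT_MET < UNKNOWN < MET."""
    rank = {ps.TriState.NOT_MET: 0, ps.TriState.UNKNOWN: 1, ps.TriState.MET: 2}
    worst = min(verdicts, key=lambda v: rank[v])
    return {
        ps.TriState.NOT_MET: ps.OverallStatus.INELIGIBLE,
        ps.TriState.UNKNOWN: ps.OverallStatus.POSSIBLE,
        ps.TriState.MET: ps.OverallStatus.ELIGIBLE,
    }[worst]


class TestCombination:
    @given(st.lists(st.sampled_from(VERDICTS), min_size=1, max_size=6))
    @settings(max_examples=200, derandomize=True)
    def test_combination_matches_min_oracle(self, verdicts):
        assert ps.combine_verdicts(verdicts) is kleene_min_oracle(verdicts)

    def test_scores_and_unknown_counts(self, fm_checklist_fixture):
        extracts, expected = build_combo_extracts(fm_checklist_fixture.criteria)
        for extract in extracts:
            for pid in extract.patient_ids():
                bundle = ps.bundle_for(extract, pid)
                result = ps.evaluate_checklist(fm_checklist_fixture, bundle, AS_OF)
                verdicts = list(expected[pid].values())
                met = verdicts.count("MET")
                assert result.score == pytest.approx(met / 4)
                assert result.unknown_count == verdicts.count("UNKNOWN")


class TestScreenPopulation:
    def test_empty_extract_gives_empty_report(self, fm_checklist_fixture):
        extract = ps.WarehouseExtract(patients=[], extract_date=AS_OF)
        report = ps.screen_population(extract, fm_checklist_fixture, AS_OF)
        assert report.results == () and report.n_screened == 0

    def test_patient_without_visit_absent_even_if_eligible(
        self, fm_checklist_fixture
    ):
        pid = "P1"
        extract = ps.WarehouseExtract(
            patients=[make_patient(pid)],
            diagnoses=[ps.DiagnosisRecord(pid, "25000", date(2011, 1, 10),
                                          is_primary=True)],
            labs=[ps.LabResult(pid, "HBA1C", 8.0, "%", date(2011, 5, 1))],
            extract_date=AS_OF,
        )
        report = ps.screen_population(extract, fm_checklist_fixture, AS_OF)
        assert report.results == () and report.n_screened == 0

    def test_clinic_filter_excludes_other_clinics(self, fm_criteria):
        cl = ps.EligibilityChecklist(
            trial_id="T", criteria=fm_criteria,
            visit_window=ps.TemporalWindow(kind="between_dates",
                                           start=AS_OF, end=date(2011, 6, 15)),
            clinics=frozenset({"FM-CLINIC-9"}),
        )
        extract = ps.WarehouseExtract(
            patients=[make_patient("P1")],
            encounters=[scheduled_visit("P1", "E1", clinic="FM-CLINIC-1")],
            extract_date=AS_OF,
        )
        assert ps.screen_population(extract, cl, AS_OF).n_screened == 0

    def test_report_ordering_and_determinism(self, fm_checklist_fixture, tmp_path):
        extracts, _ = build_combo_extracts(fm_checklist_fixture.criteria)
        for extract in extracts:
            report = ps.screen_population(extract, fm_checklist_fixture, AS_OF)
            statuses = [r.overall_status for r in report.results]
            assert ps.OverallStatus.INELIGIBLE not in statuses
            # ELIGIBLE block strictly precedes POSSIBLE block
            order = [0 if s is ps.OverallStatus.ELIGIBLE else 1 for s in statuses]
            assert order == sorted(order)
            for earlier, later in zip(report.results, report.results[1:]):
                if earlier.overall_status is later.overall_status:
                    key = (-earlier.score, earlier.unknown_count, earlier.patient_id)
                    assert key <= (-later.score, later.unknown_count, later.patient_id)
            a, b = tmp_path / "a.csv", tmp_path / "b.csv"
            ps.write_report_csv(report, a)
            ps.write_report_csv(
                ps.screen_population(extract, fm_checklist_fixture, AS_OF), b)
            assert a.read_bytes() == b.read_bytes()
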