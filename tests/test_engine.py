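"""Issue detection, parameter counting and indicator computation."""

import pytest

from rddq.config import OutlierRuleSet, RunConfig
from rddq.engine import (
    DqParameterSet,
    assess,
    classify_cases,
    compute_indicators,
    detect_ambiguous,
    detect_duplicates,
    detect_implausible_links,
    detect_missing_items,
    detect_missing_orphacodes,
    detect_missing_values,
    detect_outliers,
    relative_frequencies,
)
from rddq.model import (
    CaseDataset,
    DiagnosisRecord,
    EncounterRecord,
    PatientRecord,
)
from rddq.terminology import derive_tracers


def _diag(case, icd=None, orpha=None, cid=None, patient="p1", **kw):
    return DiagnosisRecord(case_id=case, patient_id=patient, condition_id=cid or f"d-{case}-{icd}",
                           icd_code=icd, orphacode=orpha, **kw)


def _ds(patients=(), encounters=(), diagnoses=(), **kw):
    return CaseDataset(patients=list(patients), encounters=list(encounters),
                       diagnoses=list(diagnoses), **kw)


@pytest.fixture()
def tracers(small_terminology):
    return derive_tracers(small_terminology)


class TestCaseClassification:
    def test_tracer_without_orphacode_is_rd_case(self, small_terminology):
        # Q87.5 is a tracer in the small terminology
        tracers = derive_tracers(small_terminology)
        flags = classify_cases(_ds(diagnoses=[_diag("c1", "Q87.5")]), tracers)
        assert flags.tracer == {"c1"} and flags.orpha == set()
        assert flags.rd == {"c1"}

    def test_orphacode_makes_orpha_case(self, tracers):
        flags = classify_cases(_ds(diagnoses=[_diag("c1", "E84.0", 586)]), tracers)
        assert flags.orpha == {"c1"}

    def test_empty_dataset_all_zero(self, tracers):
        flags = classify_cases(_ds(), tracers)
        assert (len(flags.rd), len(flags.orpha), len(flags.tracer)) == (0, 0, 0)

    def test_distinct_cases_counted_once(self, tracers):
        diagnoses = [_diag("c1", "Q87.5", 2097, cid="d1"), _diag("c1", "F84.2", 778, cid="d2")]
        flags = classify_cases(_ds(diagnoses=diagnoses), tracers)
        assert len(flags.rd) == 1


class TestRelativeFrequencies:
    def test_count_equal_total_gives_100000(self):
        assert relative_frequencies(20_000, 20_000, 20_000, 20_000) == (100_000,) * 3

    def test_small_count(self):
        assert relative_frequencies(5, 5, 5, 20_000)[0] == 25

    def test_half_up_rounding(self):
        # 3/200000 * 100000 = 1.5 -> 2 under half-up
        assert relative_frequencies(3, 0, 3, 200_000)[0] == 2

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_frequencies(1, 1, 1, 0)


class TestMissingItems:
    def test_items_with_no_values_anywhere(self):
        patients = [PatientRecord("p1", birth_date="1980-05-01", sex="female")]
        ds = _ds(patients=patients)
        issues, p7 = detect_missing_items(ds, ds.item_catalog)
        names = {i.group_key for i in issues}
        assert "address_city" in names and "address_postal_code" in names
        assert p7 == len(issues)

    def test_value_on_one_record_makes_item_present(self):
        patients = [
            PatientRecord("p1", address_items={"address_city": "Tbg"}),
            PatientRecord("p2"),
        ]
        ds = _ds(patients=patients)
        issues, _ = detect_missing_items(ds, ds.item_catalog)
        assert "address_city" not in {i.group_key for i in issues}


class TestMissingValues:
    def test_single_missing_discharge_date(self):
        encounters = [
            EncounterRecord(f"c{i}", "p1", "2021-01-01",
                            None if i == 0 else "2021-01-05", "IMP")
            for i in range(10)
        ]
        patients = [PatientRecord("p1", "1980-05-01", "female",
                                  {"address_city": "T", "address_postal_code": "72070"})]
        diagnoses = [_diag(f"c{i}", "E84.0", 586, cid=f"d{i}",
                           diagnosis_date="2021-01-01", role="primary") for i in range(10)]
        ds = _ds(patients, encounters, diagnoses)
        issues, p8, slots = detect_missing_values(ds, ds.item_catalog)
        assert p8 == 1
        assert issues[0].group_key == "discharge_date"
        # 1 patient x5 + 10 encounters x5 + 10 diagnoses x5
        assert slots == 5 + 50 + 50

    def test_wholly_missing_items_excluded_from_slots(self):
        patients = [PatientRecord("p1", "1980-05-01", "female")]  # no address at all
        ds = _ds(patients=patients)
        issues, p8, slots = detect_missing_values(ds, ds.item_catalog)
        assert p8 == 0
        assert slots == 3  # patient_id, birth_date, sex


class TestOutliers:
    def test_age_above_130_flagged(self):
        ds = _ds(
            patients=[PatientRecord("p1", birth_date="1890-01-01")],
            encounters=[EncounterRecord("c1", "p1", "2021-06-01", "2021-06-05")],
        )
        issues, p9, checked = detect_outliers(ds, OutlierRuleSet())
        assert p9 == 1
        assert issues[0].group_key == "age_at_admission"

    def test_age_130_not_flagged(self):
        ds = _ds(
            patients=[PatientRecord("p1", birth_date="1900-01-01")],
            encounters=[EncounterRecord("c1", "p1", "2021-06-01", None)],
        )
        _, p9, _ = detect_outliers(ds, OutlierRuleSet())
        assert p9 == 0

    def test_date_inversion_flagged(self):
        ds = _ds(encounters=[EncounterRecord("c1", "p1", "2021-06-10", "2021-06-01")])
        issues, p9, _ = detect_outliers(ds, OutlierRuleSet())
        assert p9 == 1 and issues[0].group_key == "date_order"

    def test_special_characters_in_code_field(self):
        ds = _ds(diagnoses=[DiagnosisRecord("c1", "p1", "d1", icd_code="E84.0#")])
        issues, p9, _ = detect_outliers(ds, OutlierRuleSet())
        assert p9 == 1 and issues[0].group_key == "code_characters"

    def test_absent_values_not_outliers_and_not_checked(self):
        ds = _ds(encounters=[EncounterRecord("c1", "p1", None, None)])
        _, p9, checked = detect_outliers(ds, OutlierRuleSet())
        assert p9 == 0 and checked == 0

    def test_unknown_rule_name_is_config_error(self):
        with pytest.raises(ValueError, match="unknown fields"):
            OutlierRuleSet(enabled=("age_at_admission", "nonexistent_rule"))


class TestMissingOrphacodes:
    def test_tracer_without_orphacode_counted(self, tracers):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5")])
        issues, p10, n_tracer = detect_missing_orphacodes(ds, tracers)
        assert (p10, n_tracer) == (1, 1)

    def test_non_tracer_without_orphacode_not_counted(self, tracers):
        # E84.0 is not a tracer in the small terminology
        ds = _ds(diagnoses=[_diag("c1", "E84.0")])
        _, p10, n_tracer = detect_missing_orphacodes(ds, tracers)
        assert (p10, n_tracer) == (0, 0)

    def test_all_annotated_gives_zero(self, tracers):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5", 2097), _diag("c2", "F84.2", 778)])
        _, p10, n_tracer = detect_missing_orphacodes(ds, tracers)
        assert (p10, n_tracer) == (0, 2)


class TestImplausibleLinks:
    def test_g712_777_implausible(self, small_terminology):
        ds = _ds(diagnoses=[_diag("c1", "G71.2", 777)])
        issues, p11, n_linked = detect_implausible_links(ds, small_terminology)
        assert (p11, n_linked) == (1, 1)

    def test_no_orphacodes_vacuous_denominator(self, small_terminology):
        ds = _ds(diagnoses=[_diag("c1", "G71.2")])
        _, p11, n_linked = detect_implausible_links(ds, small_terminology)
        assert (p11, n_linked) == (0, 0)

    def test_plausible_pair_not_counted(self, small_terminology):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5", 2097)])
        _, p11, n_linked = detect_implausible_links(ds, small_terminology)
        assert (p11, n_linked) == (0, 1)


class TestDuplicates:
    def test_two_identical_rows_one_surplus(self):
        ds = _ds(diagnoses=[_diag("c1", "E84.0", 586, cid="d1"),
                            _diag("c1", "E84.0", 586, cid="d2")])
        _, p12 = detect_duplicates(ds)
        assert p12 == 1

    def test_all_unique_zero(self):
        ds = _ds(diagnoses=[_diag("c1", "E84.0", 586), _diag("c2", "E84.0", 586)])
        assert detect_duplicates(ds)[1] == 0

    def test_group_sizes_3_and_2_give_3(self):
        diagnoses = [_diag("c1", "E84.0", 586, cid=f"a{i}") for i in range(3)]
        diagnoses += [_diag("c2", "Q87.5", 2097, cid=f"b{i}") for i in range(2)]
        ds = _ds(diagnoses=diagnoses)
        assert detect_duplicates(ds)[1] == 3

    def test_orphacode_distinguishes_groups(self):
        ds = _ds(diagnoses=[_diag("c1", "F84.2", 778, cid="d1"),
                            _diag("c1", "F84.2", 3095, cid="d2")])
        assert detect_duplicates(ds)[1] == 0


class TestAmbiguity:
    def test_multi_rd_code_without_orphacode_ambiguous(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "F84.2")])
        issues, p13 = detect_ambiguous(ds, small_terminology, tracers)
        assert p13 == 1 and issues[0].group_key == "F84.2"

    def test_resolved_multi_rd_code_unambiguous(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5", 2097)])
        assert detect_ambiguous(ds, small_terminology, tracers)[1] == 0

    def test_single_candidate_tracer_unambiguous(self, small_terminology, tracers):
        # G71.2 has exactly one candidate Orphacode
        assert "G71.2" in tracers
        ds = _ds(diagnoses=[_diag("c1", "G71.2")])
        assert detect_ambiguous(ds, small_terminology, tracers)[1] == 0

    def test_case_counted_once(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "F84.2", cid="d1"), _diag("c1", "Q87.5", cid="d2")])
        assert detect_ambiguous(ds, small_terminology, tracers)[1] == 1

    def test_rule_b_implausible_on_multi_code(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "F84.2", 999999)])
        assert detect_ambiguous(ds, small_terminology, tracers, rule_b=True)[1] == 1
        assert detect_ambiguous(ds, small_terminology, tracers, rule_b=False)[1] == 0


class TestIndicators:
    def test_printed_unambiguity_example(self):
        params = DqParameterSet(rd_cases=163, tracer_cases=163, ambiguous_cases=9,
                                n_case_records=163)
        value = compute_indicators(params).dqi_un_cur.value
        assert value == pytest.approx(94.478, abs=0.001)
        assert value > 94

    def test_printed_plausibility_example(self):
        params = DqParameterSet(rd_cases=783, orpha_cases=729, tracer_cases=165,
                                implausible_links=21, n_linked_diagnoses=729,
                                n_case_records=783)
        value = compute_indicators(params).dqi_pl_opr.value
        assert value == pytest.approx(97.119, abs=0.001)
        assert value > 97

    def test_no_issues_all_100(self):
        params = DqParameterSet(
            rd_cases=10, orpha_cases=10, tracer_cases=10,
            n_mandatory_items=15, n_value_slots=100, n_checked_values=30,
            n_tracer_diagnoses=10, n_linked_diagnoses=10, n_case_records=10,
        )
        indicators = compute_indicators(params)
        assert all(i.value == 100.0 and i.evaluable for i in indicators.as_dict().values())

    def test_all_issue_limit_is_zero(self):
        params = DqParameterSet(
            rd_cases=5, orpha_cases=0, tracer_cases=5, ambiguous_cases=5,
            missing_orphacodes=10, n_tracer_diagnoses=10, n_case_records=10,
            duplicate_cases=10,
        )
        indicators = compute_indicators(params)
        assert indicators.dqi_un_cur.value == 0.0
        assert indicators.dqi_co_ocr.value == 0.0
        assert indicators.dqi_un_cdr.value == 0.0

    def test_vacuous_denominator_reports_zero_flagged(self):
        params = DqParameterSet()
        indicators = compute_indicators(params)
        assert indicators.dqi_co_ocr.value == 0.0
        assert not indicators.dqi_co_ocr.evaluable

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            DqParameterSet(missing_items=-1)

    def test_case_count_consistency_enforced(self):
        with pytest.raises(ValueError, match="P1"):
            DqParameterSet(rd_cases=5, orpha_cases=1, tracer_cases=1)

    @pytest.mark.parametrize("field,denominator", [
        ("missing_orphacodes", "n_tracer_diagnoses"),
        ("implausible_links", "n_linked_diagnoses"),
        ("duplicate_cases", "n_case_records"),
    ])
    def test_adding_an_issue_never_increases_indicator(self, field, denominator):
        base = dict(rd_cases=10, orpha_cases=10, tracer_cases=10,
                    n_tracer_diagnoses=20, n_linked_diagnoses=20, n_case_records=20,
                    n_mandatory_items=15, n_value_slots=50, n_checked_values=50)
        for count in range(0, 20):
            lo = compute_indicators(DqParameterSet(**base, **{field: count}))
            hi = compute_indicators(DqParameterSet(**base, **{field: count + 1}))
            for name in lo.as_dict():
                assert hi.as_dict()[name].value <= lo.as_dict()[name].value


class TestAssessPipeline:
    def test_issue_total_consistency(self, small_terminology, tracers):
        patients = [PatientRecord("p1", "1890-01-01", "female",
                                  {"address_city": "T", "address_postal_code": "1"})]
        encounters = [EncounterRecord("c1", "p1", "2021-06-01", "2021-05-01", "IMP")]
        diagnoses = [
            _diag("c1", "Q87.5", cid="d1", diagnosis_date="2021-06-01", role="primary"),
            _diag("c1", "G71.2", 777, cid="d2", diagnosis_date="2021-06-01", role="secondary"),
            _diag("c1", "G71.2", 777, cid="d3", diagnosis_date="2021-06-01", role="secondary"),
        ]
        ds = _ds(patients, encounters, diagnoses)
        params, indicators, issues = assess(ds, small_terminology, tracers)
        assert len(issues) == params.issue_total
        assert all(0 <= i.value <= 100 for i in indicators.as_dict().values())

    def test_relative_frequencies_absent_without_total(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5", 2097)])
        params, _, _ = assess(ds, small_terminology, tracers)
        assert params.rd_cases_rel is None

    def test_fingerprint_set(self, small_terminology, tracers):
        ds = _ds(diagnoses=[_diag("c1", "Q87.5", 2097)])
        params, _, _ = assess(ds, small_terminology, tracers)
        assert params.fingerprint
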