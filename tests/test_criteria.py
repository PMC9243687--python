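"""Criteria engine: predicate semantics, combinators, provenance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnmkit import (
    Cohort,
    ConfigurationError,
    PatientRecord,
    classify,
    classify_cohort,
    evaluate_predicate,
    load_builtin,
    pltc_screen,
)
from mnmkit.criteria import Threshold, criteria_from_dict

from oracle import naive_classify, random_record


def _predicate(criteria, predicate_id):
    return next(p for p in criteria.predicates if p.predicate_id == predicate_id)


class TestEvaluatePredicate:
    @pytest.mark.parametrize(
        "predicate_id, record, expected",
        [
            # severe thrombocytopenia below the < 50 000 cut-off
            ("who_lab_thrombocytopenia",
             PatientRecord("r", measurements={"platelet_count_per_mm3": 40_000.0}), True),
            ("who_lab_thrombocytopenia",
             PatientRecord("r", measurements={"platelet_count_per_mm3": 50_000.0}), False),
            # transfusion of five or more units meets the WHO criterion
            ("who_mgmt_transfusion_ge5", PatientRecord("r", transfusion_units=5), True),
            ("who_mgmt_transfusion_ge5", PatientRecord("r", transfusion_units=4), False),
            # respiratory rate inside (6, 40) is unremarkable
            ("who_clin_resp_rate",
             PatientRecord("r", measurements={"respiratory_rate_per_min": 30.0}), False),
            ("who_clin_resp_rate",
             PatientRecord("r", measurements={"respiratory_rate_per_min": 41.0}), True),
            ("who_clin_resp_rate",
             PatientRecord("r", measurements={"respiratory_rate_per_min": 5.0}), True),
            # compound jaundice-with-pre-eclampsia: single flag or conjunction
            ("who_clin_jaundice_preeclampsia",
             PatientRecord("r", flags={"jaundice", "preeclampsia"}), True),
            ("who_clin_jaundice_preeclampsia", PatientRecord("r", flags={"jaundice"}), False),
            ("who_clin_jaundice_preeclampsia",
             PatientRecord("r", flags={"jaundice_with_preeclampsia"}), True),
        ],
    )
    def test_who_predicate_examples(self, who, predicate_id, record, expected):
        assert evaluate_predicate(record, _predicate(who, predicate_id)) is expected

    def test_empty_record_fails_every_shipped_predicate(self, all_sets):
        """Missingness rule: absence of data never asserts severity."""
        empty = PatientRecord("empty")
        for criteria in all_sets + [load_builtin("pltc_screen")]:
            for predicate in criteria.predicates:
                assert evaluate_predicate(empty, predicate) is False, predicate.predicate_id

    def test_unknown_token_is_a_configuration_error(self, vocab):
        doc = {
            "set_id": "who_2011",
            "combinator": "any_one",
            "predicates": [
                {"predicate_id": "bad_pred", "category": "clinical",
                 "expression": {"flag": "no_such_token"}}
            ],
        }
        with pytest.raises(ConfigurationError, match="bad_pred"):
            criteria_from_dict(doc, vocab)


class TestClassify:
    def test_transfusion_only_survivor_across_sets(self):
        """Six units transfused, nothing else: WHO and any-volume sets call
        it a near miss, the condition-based Waterstone set does not."""
        record = PatientRecord("w", transfusion_units=6)
        who_result = classify(record, load_builtin("who_2011"))
        assert who_result.positive and who_result.verdict == "near_miss"
        assert who_result.matched == ("who_mgmt_transfusion_ge5",)
        assert not classify(record, load_builtin("waterstone_2001")).positive
        assert classify(record, load_builtin("global_network_2016")).positive

    def test_death_without_matching_indicator_is_missed(self):
        record = PatientRecord("d", outcome="died", flags={"severe_preeclampsia"})
        result = classify(record, load_builtin("mantel_1998"))
        assert not result.positive
        assert result.verdict == "maternal_death_missed"
        # the same record is identified by the condition-based set
        assert classify(record, load_builtin("waterstone_2001")).verdict == (
            "maternal_death_identified"
        )

    def test_indian_rule_needs_all_three_sections(self):
        partial = PatientRecord(
            "i1", flags={"shock"}, measurements={"platelet_count_per_mm3": 30_000.0}
        )
        indian = load_builtin("indian_2014")
        assert not classify(partial, indian).positive
        complete = PatientRecord(
            "i2",
            flags={"shock", "hysterectomy"},
            measurements={"platelet_count_per_mm3": 30_000.0},
        )
        assert classify(complete, indian).positive

    def test_indian_collapse_shortcut(self):
        record = PatientRecord("i3", flags={"cardiac_arrest"})
        result = classify(record, load_builtin("indian_2014"))
        assert result.positive

    def test_matched_is_sorted_and_consistent_with_positive(self, default_cohort, all_sets):
        for criteria in all_sets:
            for result in classify_cohort(default_cohort, criteria):
                assert list(result.matched) == sorted(result.matched)
                if criteria.combinator == "any_one":
                    assert result.positive == bool(result.matched)

    def test_cohort_classification_is_pure_and_order_preserving(self, default_cohort, who):
        first = classify_cohort(default_cohort, who)
        second = classify_cohort(default_cohort, who)
        assert first == second
        assert [r.record_id for r in first] == [r.record_id for r in default_cohort]

    def test_empty_cohort(self, who):
        assert classify_cohort(Cohort(records=[], live_births=1), who) == []

    def test_identical_records_get_identical_verdicts(self, who):
        base = dict(flags={"shock"}, transfusion_units=2)
        cohort = Cohort(
            records=[PatientRecord(f"c{i}", **base) for i in range(3)], live_births=10
        )
        verdicts = {r.verdict for r in classify_cohort(cohort, who)}
        assert verdicts == {"near_miss"}

    def test_section_combinator_requires_sections(self):
        doc = {
            "set_id": "custom",
            "combinator": "indian_sections",
            "predicates": [
                {"predicate_id": "p1", "category": "clinical",
                 "expression": {"flag": "shock"}}
            ],
        }
        with pytest.raises(ConfigurationError, match="section"):
            criteria_from_dict(doc)


class TestTransfusionNesting:
    def test_who_ge5_positive_implies_global_network_positive(self):
        for units in (5, 6, 9):
            record = PatientRecord("t", transfusion_units=units)
            assert classify(record, load_builtin("who_2011")).positive
            assert classify(record, load_builtin("global_network_2016")).positive

    def test_low_volume_transfusion_splits_the_sets(self):
        for units in (1, 2, 3, 4):
            record = PatientRecord("t", transfusion_units=units)
            assert not classify(record, load_builtin("who_2011")).positive
            assert classify(record, load_builtin("global_network_2016")).positive


class TestPltcScreen:
    def test_screening_threshold_looser_than_near_miss(self, who):
        record = PatientRecord("p", measurements={"platelet_count_per_mm3": 90_000.0})
        assert pltc_screen(record) == {"systemic"}
        assert not classify(record, who).positive

    def test_eclampsia_is_hypertensive(self):
        assert pltc_screen(PatientRecord("p", flags={"eclampsia"})) == {"hypertensive"}

    def test_empty_record_screens_negative(self):
        assert pltc_screen(PatientRecord("p")) == set()

    def test_multiple_categories(self):
        record = PatientRecord(
            "p", flags={"postpartum_haemorrhage", "severe_preeclampsia"},
            transfusion_units=2,
        )
        assert pltc_screen(record) == {"haemorrhagic", "hypertensive", "management"}


class TestOracleEquivalence:
    def test_engine_matches_naive_evaluator_on_random_records(self, vocab, all_sets):
        """Classification agrees with a brute-force evaluator that
        enumerates every predicate without short-circuiting."""
        rng = np.random.default_rng(11)
        sets = all_sets + [load_builtin("pltc_screen")]
        for i in range(2000):
            record = random_record(rng, vocab, f"r{i}")
            for criteria in sets:
                result = classify(record, criteria)
                positive, matched, verdict = naive_classify(record, criteria)
                assert (result.positive, result.matched, result.verdict) == (
                    positive, matched, verdict
                ), (record, criteria.set_id)


class TestThresholdMonotonicity:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        value=st.floats(0, 200_000, allow_nan=False),
        cut=st.floats(1, 100_000),
        bump=st.floats(0, 50_000),
        cmp=st.sampled_from([">", ">="]),
    )
    def test_raising_a_cutoff_never_creates_a_positive(self, value, cut, bump, cmp):
        record = PatientRecord("m", measurements={"platelet_count_per_mm3": value})
        low = Threshold("platelet_count_per_mm3", cmp, cut)
        high = Threshold("platelet_count_per_mm3", cmp, cut + bump)
        from mnmkit.criteria import _evaluate

        if not _evaluate(low, record):
            assert not _evaluate(high, record)
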