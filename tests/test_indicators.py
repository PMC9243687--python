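"""Process indicators: definitions, rounding, structural properties."""

import pytest

from mnmkit import (
    Cohort,
    PatientRecord,
    case_fatality_table,
    compare_criteria,
    compute_mmr,
    compute_report,
    load_builtin,
    pltc_incidence,
    report_from_counts,
    round_half_away,
)
from mnmkit.criteria import classify_cohort


class TestReportFromCounts:
    @pytest.mark.parametrize(
        "mnm, md, lb, mnm_ratio, smo_ratio, mi, ratio2dp",
        [
            (323, 57, 37_590, 8.6, 10.1, 15.0, 5.67),
            (324, 48, 37_590, 8.6, 9.9, 12.9, 6.75),
            (483, 57, 37_590, 12.8, 14.4, 10.6, 8.47),
        ],
    )
    def test_reference_count_combinations(self, mnm, md, lb, mnm_ratio, smo_ratio, mi, ratio2dp):
        report = report_from_counts("x", mnm, md, lb)
        assert round_half_away(report.mnm_ratio_per_1000, 1) == mnm_ratio
        assert round_half_away(report.smo_ratio_per_1000, 1) == smo_ratio
        assert round_half_away(report.mortality_index_pct, 1) == mi
        assert round_half_away(report.mnm_to_md_ratio, 2) == ratio2dp

    def test_empty_cohort_counts(self):
        report = report_from_counts("x", 0, 0, 1000)
        assert report.mnm_ratio_per_1000 == 0.0
        assert report.smo_ratio_per_1000 == 0.0
        assert report.mortality_index_pct == 0.0
        assert report.mnm_to_md_ratio is None
        assert report.presentation()["rounded"]["mnm_to_md_ratio"] is None

    def test_zero_live_births_is_a_domain_error(self):
        with pytest.raises(ValueError):
            report_from_counts("x", 1, 1, 0)

    def test_smo_is_near_miss_plus_identified_deaths(self):
        report = report_from_counts("x", 10, 3, 500, n_deaths_missed=2)
        assert report.n_smo == 13
        assert report.n_deaths_missed == 2

    def test_scale_equivariance(self):
        base = report_from_counts("x", 40, 8, 10_000)
        scaled = report_from_counts("x", 400, 80, 100_000)
        assert base.mnm_ratio_per_1000 == pytest.approx(scaled.mnm_ratio_per_1000)
        assert base.smo_ratio_per_1000 == pytest.approx(scaled.smo_ratio_per_1000)
        assert base.mortality_index_pct == pytest.approx(scaled.mortality_index_pct)
        assert base.mnm_to_md_ratio == pytest.approx(scaled.mnm_to_md_ratio)

    def test_quality_of_care_direction(self):
        """Holding deaths fixed, more near misses means a lower mortality
        index and a higher near-miss-to-death ratio."""
        previous = report_from_counts("x", 100, 20, 10_000)
        for mnm in range(101, 160, 7):
            current = report_from_counts("x", mnm, 20, 10_000)
            assert current.mortality_index_pct < previous.mortality_index_pct
            assert current.mnm_to_md_ratio > previous.mnm_to_md_ratio
            previous = current


class TestRates:
    def test_mmr_definition(self):
        assert round_half_away(compute_mmr(57, 37_590), 1) == 151.6
        assert compute_mmr(0, 500) == 0.0
        assert compute_mmr(1, 100_000) == 1.0

    def test_pltc_incidence_definition(self):
        assert round_half_away(pltc_incidence(1833, 37_590), 1) == 48.8
        assert pltc_incidence(0, 37_590) == 0.0
        assert pltc_incidence(37_590, 37_590) == 1000.0

    def test_rates_reject_zero_denominator(self):
        with pytest.raises(ValueError):
            compute_mmr(1, 0)
        with pytest.raises(ValueError):
            pltc_incidence(1, 0)


class TestComputeReport:
    def test_conservation_of_deaths_for_every_set(self, default_cohort, all_sets):
        outcomes = default_cohort.outcomes()
        total_deaths = sum(1 for o in outcomes.values() if o == "died")
        for criteria in all_sets:
            results = classify_cohort(default_cohort, criteria)
            report = compute_report(results, outcomes, default_cohort.live_births)
            assert report.n_deaths_identified + report.n_deaths_missed == total_deaths

    def test_missing_outcome_is_an_error(self, who):
        record = PatientRecord("w", transfusion_units=6)
        results = classify_cohort(Cohort([record], live_births=10), who)
        with pytest.raises(ValueError, match="outcome"):
            compute_report(results, {}, 10)


class TestCaseFatality:
    def _cohort(self):
        records = []
        for i in range(90):  # postpartum haemorrhage: 12 deaths
            records.append(
                PatientRecord(
                    f"pph{i}",
                    outcome="died" if i < 12 else "survived",
                    condition_category={"haemorrhage"},
                    flags={"postpartum_haemorrhage"},
                )
            )
        for i in range(21):  # ectopic pregnancy: no deaths
            records.append(
                PatientRecord(
                    f"ect{i}", condition_category={"haemorrhage"},
                    flags={"ectopic_pregnancy"},
                )
            )
        return Cohort(records, live_births=1000)

    def test_case_fatality_percentages(self):
        rows = case_fatality_table(self._cohort(), condition_categories=["haemorrhage"])
        (row,) = rows
        assert row.n_pltc == 111 and row.n_deaths == 12
        assert round_half_away(row.case_fatality_pct, 1) == 10.8

    def test_sub_condition_rates_from_counts(self):
        # closed-form: deaths / women with the condition x 100
        assert round_half_away(12 / 90 * 100, 1) == 13.3
        assert 0 / 21 * 100 == 0.0

    def test_condition_without_members_is_omitted(self):
        rows = case_fatality_table(self._cohort(), condition_categories=["infection"])
        assert rows == []

    def test_overlapping_categories_count_in_each(self):
        record = PatientRecord(
            "both", condition_category={"haemorrhage", "hypertensive"},
            outcome="died",
        )
        cohort = Cohort([record], live_births=10)
        rows = case_fatality_table(cohort)
        assert {r.condition for r in rows} == {"haemorrhage", "hypertensive"}
        assert all(r.case_fatality_pct == 100.0 for r in rows)


class TestCompareCriteria:
    def test_single_record_comparison(self):
        cohort = Cohort([PatientRecord("w", transfusion_units=6)], live_births=1000)
        reports = compare_criteria(
            cohort, [load_builtin("who_2011"), load_builtin("waterstone_2001")]
        )
        by_id = {r.set_id: r for r in reports}
        assert by_id["who_2011"].n_near_miss == 1
        assert by_id["waterstone_2001"].n_near_miss == 0

    def test_empty_cohort_yields_zero_reports(self, all_sets):
        reports = compare_criteria(Cohort([], live_births=100), all_sets)
        assert len(reports) == len(all_sets)
        assert all(r.n_smo == 0 and r.mnm_to_md_ratio is None for r in reports)

    def test_ordering_is_by_set_id(self, default_cohort, all_sets):
        reports = compare_criteria(default_cohort, all_sets)
        assert [r.set_id for r in reports] == sorted(r.set_id for r in reports)


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [(0.15, 1, 0.2), (0.25, 1, 0.3), (8.85, 1, 8.9), (5.666, 2, 5.67), (-0.15, 1, -0.2)],
    )
    def test_half_away_from_zero(self, value, ndigits, expected):
        assert round_half_away(value, ndigits) == expected
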