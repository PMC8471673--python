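"""PASO outcome classification, prevalence arithmetic, and association statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aldoprio.cohort import (
    PatientRecord,
    assign_carrier_status,
    classify_biochemical_outcome,
    classify_clinical_outcome,
    contingency_test,
    crude_odds_ratio,
    final_bapwv,
    multinomial_lr_tests,
    outcome_crosstab,
    prevalence_summary,
)
from aldoprio.consensus import classify_table
from aldoprio.datasets import (
    BIOCHEMICAL_OUTCOME_COUNTS,
    CLINICAL_OUTCOME_COUNTS,
    COMBINED_CARRIER_2X2,
    CRUDE_OR_2X2,
    SANGER_POSITIVE_COUNTS,
)

from oracles import fisher_2x2_enumeration


def make_patient(**overrides):
    base = dict(
        sample_id="P1",
        sbp=150.0, dbp=95.0, aldosterone=50.0,
        n_antihypertensives_pre=2,
        sbp_post=128.0, dbp_post=80.0, n_antihypertensives_post=0,
        potassium_post=4.0, arr_post=20.0, aldosterone_post=10.0,
        confirmatory_test_improved=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestClinicalOutcome:
    # pre-surgery BP 150/95 on 2 drugs; threshold 140/90
    @pytest.mark.parametrize(
        "sbp_post, dbp_post, meds_post, expected",
        [
            (128, 80, 0, "complete"),   # normalized, no drugs
            (140, 80, 0, "partial"),    # systolic at threshold is not normal
            (128, 90, 0, "partial"),    # diastolic at threshold is not normal
            (128, 80, 1, "partial"),    # normalized but still medicated
            (150, 95, 1, "partial"),    # same BP, fewer drugs
            (150, 95, 2, "absent"),     # same BP, same drugs
            (150, 90, 2, "partial"),    # diastolic reduced, same drugs
            (155, 95, 0, "absent"),     # BP rose despite stopping drugs
            (160, 80, 2, "absent"),     # one component up, one down
            (150, 95, 3, "absent"),     # same BP, more drugs
        ],
    )
    def test_boundary_grid(self, sbp_post, dbp_post, meds_post, expected):
        rec = make_patient(sbp_post=float(sbp_post), dbp_post=float(dbp_post),
                           n_antihypertensives_post=meds_post)
        assert classify_clinical_outcome(rec) == expected

    def test_missing_post_fields_is_error(self):
        rec = make_patient(sbp_post=None)
        with pytest.raises(ValueError, match="sbp_post"):
            classify_clinical_outcome(rec)

    def test_threshold_is_configurable(self):
        rec = make_patient(sbp_post=128.0, dbp_post=80.0,
                           n_antihypertensives_post=0)
        assert classify_clinical_outcome(rec, bp_threshold=(125.0, 80.0)) != "complete"


class TestBiochemicalOutcome:
    # baseline aldosterone 50 ng/dL; thresholds ARR < 38, K >= 3.5
    @pytest.mark.parametrize(
        "k_post, arr_post, aldo_post, improved, expected",
        [
            (4.0, 20.0, 10.0, False, "complete"),
            (3.5, 37.9, 40.0, False, "complete"),   # both boundaries inclusive side
            (3.5, 38.0, 20.0, False, "partial"),    # ARR at cutoff, >=50% aldo fall
            (3.5, 38.0, 25.0, False, "partial"),    # fall of exactly 50% qualifies
            (3.5, 38.0, 26.0, False, "absent"),     # fall below 50%, no better test
            (3.5, 38.0, 26.0, True, "partial"),     # improved confirmatory test
            (3.49, 20.0, 10.0, False, "absent"),    # hypokalemia uncorrected
            (3.0, 100.0, 20.0, True, "absent"),
        ],
    )
    def test_boundary_grid(self, k_post, arr_post, aldo_post, improved, expected):
        rec = make_patient(potassium_post=k_post, arr_post=arr_post,
                           aldosterone_post=aldo_post,
                           confirmatory_test_improved=improved)
        assert classify_biochemical_outcome(rec) == expected

    def test_missing_post_fields_is_error(self):
        with pytest.raises(ValueError, match="arr_post"):
            classify_biochemical_outcome(make_patient(arr_post=None))


class TestFinalBapwv:
    def test_max_of_side_means(self):
        rec = make_patient(bapwv_right=(1600.0, 1640.0), bapwv_left=(1700.0, 1720.0))
        assert final_bapwv(rec) == 1710.0

    def test_equal_sides_return_common_mean(self):
        rec = make_patient(bapwv_right=(1600.0, 1640.0), bapwv_left=(1640.0, 1600.0))
        assert final_bapwv(rec) == 1620.0

    def test_randomized_pairs_match_direct_recomputation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            r = tuple(rng.uniform(1000, 2500, size=2))
            l = tuple(rng.uniform(1000, 2500, size=2))
            rec = make_patient(bapwv_right=r, bapwv_left=l)
            assert final_bapwv(rec) == max(sum(r) / 2, sum(l) / 2)

    def test_missing_side_is_error(self):
        with pytest.raises(ValueError, match="baPWV"):
            final_bapwv(make_patient(bapwv_right=(1600.0, 1640.0)))


class TestCarrierAssignment:
    def test_fixture_calls_split_75_into_21_and_54(self, table1, cutoffs):
        calls = classify_table(table1, cutoffs)
        cohort = [make_patient(sample_id=f"NGS{i:02d}") for i in range(1, 76)]
        assigned = assign_carrier_status(cohort, calls, sanger={})
        groups = [r.genotype_group for r in assigned]
        assert groups.count("ngs_carrier") == 21
        assert groups.count("non_carrier") == 54

    def test_empty_calls_all_non_carrier(self):
        cohort = [make_patient(sample_id=f"P{i}") for i in range(5)]
        assigned = assign_carrier_status(cohort, [], sanger={})
        assert all(r.genotype_group == "non_carrier" for r in assigned)

    def test_sample_in_both_sources_is_contract_violation(self, table1, cutoffs):
        calls = classify_table(table1, cutoffs)
        cohort = [make_patient(sample_id="NGS01")]
        with pytest.raises(ValueError, match="NGS01"):
            assign_carrier_status(cohort, calls, sanger={"NGS01": "KCNJ5"})

    def test_sample_counted_once_despite_multiple_variants(self, table1, cutoffs):
        doubled = classify_table(table1, cutoffs)
        extra = [c for c in doubled if c.sample_id == "NGS01"]
        assigned = assign_carrier_status(
            [make_patient(sample_id="NGS01")], doubled + extra, sanger={}
        )
        assert assigned[0].genotype_group == "ngs_carrier"


class TestPrevalence:
    def test_published_arithmetic(self, table1, cutoffs):
        calls = classify_table(table1, cutoffs)
        prev = prevalence_summary(SANGER_POSITIVE_COUNTS, calls, n_total=240)
        assert prev.n_carriers == 186
        assert prev.overall_percent == pytest.approx(77.5)
        assert prev.per_gene["CTNNB1"][0] == 11
        assert prev.per_gene["KCNJ5"][0] == 151
        assert prev.per_gene["ATP1A1"][0] == 5

    def test_empty_inputs_all_zero(self):
        prev = prevalence_summary({}, [], n_total=10)
        assert prev.n_carriers == 0 and prev.overall_percent == 0.0

    def test_total_below_carriers_is_error(self, table1, cutoffs):
        calls = classify_table(table1, cutoffs)
        with pytest.raises(ValueError):
            prevalence_summary(SANGER_POSITIVE_COUNTS, calls, n_total=100)


class TestContingency:
    def test_published_clinical_table(self):
        res = contingency_test(CLINICAL_OUTCOME_COUNTS)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.010, abs=1e-3)

    def test_published_biochemical_table(self):
        res = contingency_test(BIOCHEMICAL_OUTCOME_COUNTS)
        assert res.p_value == pytest.approx(0.440, abs=5e-3)

    def test_combined_carrier_table_highly_significant(self):
        assert contingency_test(COMBINED_CARRIER_2X2).p_value < 1e-4

    def test_identical_group_proportions_give_null_result(self):
        res = contingency_test([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_error_names_the_margin(self):
        with pytest.raises(ValueError, match="column"):
            contingency_test([[5, 0], [7, 0]])
        with pytest.raises(ValueError, match="row"):
            contingency_test([[0, 0], [7, 3]])

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            contingency_test(CLINICAL_OUTCOME_COUNTS, test="fisher_exact")

    def test_chi2_equals_squared_two_proportion_z(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            res = contingency_test([[a, b], [c, d]])
            n1, n2 = a + b, c + d
            p1, p2 = a / n1, c / n2
            pooled = (a + c) / (n1 + n2)
            z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            assert res.statistic == pytest.approx(z**2, rel=1e-9)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            table = rng.integers(1, 25, size=(2, 2))
            res = contingency_test(table, test="fisher_exact")
            assert res.p_value == pytest.approx(
                fisher_2x2_enumeration(table), rel=1e-8
            )


class TestOddsRatio:
    def test_published_counts_give_or_5(self):
        res = crude_odds_ratio(CRUDE_OR_2X2)
        assert res.odds_ratio == pytest.approx(5.0)
        assert res.ci_low < 5.0 < res.ci_high

    def test_symmetric_table_or_1(self):
        assert crude_odds_ratio([[1, 1], [1, 1]]).odds_ratio == pytest.approx(1.0)

    def test_random_tables_match_direct_formula(self):
        rng = np.random.default_rng(21)
        z = stats.norm.ppf(0.975)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
            res = crude_odds_ratio([[a, b], [c, d]])
            assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-12)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert res.ci_low == pytest.approx(
                math.exp(math.log(a * d / (b * c)) - z * se), rel=1e-9
            )

    def test_zero_cell_uses_haldane_correction(self):
        res = crude_odds_ratio([[5, 0], [3, 7]])
        expected = (5.5 * 7.5) / (0.5 * 3.5)
        assert res.odds_ratio == pytest.approx(expected)
        assert math.isfinite(res.ci_high)


class TestOutcomeCrosstab:
    def test_crosstab_reproduces_manual_counts(self):
        cohort = []
        layout = [("carrier", "complete", 4), ("carrier", "absent", 2),
                  ("non_carrier", "complete", 3), ("non_carrier", "absent", 5)]
        i = 0
        for group, outcome, n in layout:
            for _ in range(n):
                i += 1
                kwargs = dict(
                    sample_id=f"P{i}",
                    genotype_group="ngs_carrier" if group == "carrier" else "non_carrier",
                )
                if outcome == "absent":
                    kwargs.update(sbp_post=160.0, dbp_post=100.0,
                                  n_antihypertensives_post=2)
                cohort.append(make_patient(**kwargs))
        res = outcome_crosstab(
            cohort, lambda r: "carrier" if r.is_carrier else "non_carrier",
            outcome="clinical",
        )
        assert res.table.tolist() == [[4, 2], [3, 5]]


@pytest.fixture(scope="module")
def planted_frame():
    rng = np.random.default_rng(17)
    n = 300
    carrier = (rng.random(n) < 0.28).astype(float)
    age = rng.normal(54.5, 10.6, n)
    probs = np.where(
        carrier[:, None].astype(bool),
        np.array([0.714, 0.143, 0.143]),
        np.array([0.333, 0.426, 0.241]),
    )
    labels = np.array(["complete", "partial", "absent"])
    outcome = [labels[rng.choice(3, p=p)] for p in probs]
    return pd.DataFrame({"outcome": outcome, "carrier": carrier, "age": age})


class TestMultinomialLR:
    def test_planted_carrier_effect_detected(self, planted_frame):
        report = multinomial_lr_tests(planted_frame, "outcome", ["carrier", "age"])
        assert report.per_covariate["carrier"].p_value < 0.05
        assert report.per_covariate["carrier"].df == 2
        assert report.converged

    def test_statistics_non_negative_and_p_in_unit_interval(self, planted_frame):
        report = multinomial_lr_tests(planted_frame, "outcome", ["carrier", "age"])
        for res in report.per_covariate.values():
            assert res.chi2 >= 0.0
            assert 0.0 <= res.p_value <= 1.0
        assert report.overall_chi2 >= 0.0

    def test_identically_zero_covariate_has_no_effect(self, planted_frame):
        frame = planted_frame.assign(flat=0.0)
        report = multinomial_lr_tests(frame, "outcome", ["carrier", "flat"])
        assert report.per_covariate["flat"].chi2 == pytest.approx(0.0, abs=1e-4)
        assert report.per_covariate["flat"].p_value == pytest.approx(1.0, abs=1e-3)

    def test_listwise_deletion_is_logged(self, planted_frame):
        frame = planted_frame.copy()
        frame.loc[:4, "age"] = np.nan
        report = multinomial_lr_tests(frame, "outcome", ["carrier", "age"])
        assert report.n_dropped == 5
        assert report.n_used == len(frame) - 5

    def test_two_level_outcome_rejected(self, planted_frame):
        frame = planted_frame[planted_frame["outcome"] != "partial"]
        with pytest.raises(ValueError, match="3 observed levels"):
            multinomial_lr_tests(frame, "outcome", ["carrier"])
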