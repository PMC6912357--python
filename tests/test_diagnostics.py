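"""Unit tests for case definitions, exact CIs, 2x2 metrics and association."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bluesclera import (
    ContingencyTable2x2,
    build_contingency,
    classify_anemia,
    classify_blue,
    classify_iron_status,
    clopper_pearson,
    diagnostic_metrics,
)
from bluesclera.diagnostics import association_test


class TestClassifyIronStatus:
    def test_low_ferritin_is_id(self):
        assert classify_iron_status(25, tps=30) is True

    def test_low_saturation_with_moderate_ferritin_is_id(self):
        assert classify_iron_status(250, tps=10) is True

    def test_high_ferritin_low_tps_is_nid_without_inflammation(self):
        assert classify_iron_status(400, tps=10) is False

    def test_inflammatory_ferritin_window(self):
        assert classify_iron_status(80, inflammation=True) is True
        assert classify_iron_status(80, inflammation=False) is False
        # inflammation derived from CRP when the flag is absent
        assert classify_iron_status(80, crp=12.0) is True
        assert classify_iron_status(80, crp=2.0) is False

    def test_missing_tps_leaves_ferritin_clauses(self):
        assert classify_iron_status(25) is True
        assert classify_iron_status(200) is False

    def test_missing_ferritin_rejected(self):
        with pytest.raises(ValueError):
            classify_iron_status(float("nan"))


class TestClassifyBlue:
    def test_single_rater_definition(self):
        assert classify_blue((3, 2, 1), "r1") is True
        assert classify_blue((3, 2, 1), "r2") is False

    def test_consensus_counts_two_of_three(self):
        assert classify_blue((3, 3, 1), "consensus") is True
        assert classify_blue((3, 2, 2), "consensus") is False

    def test_maximal_grades_blue_under_any_rule(self):
        for rule in ("r1", "r2", "r3", "consensus"):
            assert classify_blue((4, 4, 4), rule) is True

    def test_grade_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_blue((0, 2, 3), "r1")
        with pytest.raises(ValueError):
            classify_blue((1, 2, 5), "consensus")

    @given(st.tuples(*[st.integers(1, 4)] * 3))
    def test_consensus_equals_majority_count(self, grades):
        assert classify_blue(grades, "consensus") == (
            sum(g >= 3 for g in grades) >= 2)


class TestClassifyAnemia:
    @pytest.mark.parametrize("hb,sex,expected", [
        (12.0, "F", True), (12.5, "F", False), (12.5, "M", True),
        (13.0, "M", True), (13.1, "M", False),
    ])
    def test_sex_specific_inclusive_thresholds(self, hb, sex, expected):
        assert classify_anemia(hb, sex) is expected

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            classify_anemia(12.0, "X")


class TestContingency:
    def test_counts_against_true_status(self):
        df = pd.DataFrame({
            "grade_r1": [3, 3, 1, 2], "grade_r2": [1, 4, 1, 3],
            "grade_r3": [1, 4, 2, 3], "true_id": [True, True, False, False],
        })
        t = build_contingency(df, "r1", reference="true")
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 2)
        t = build_contingency(df, "consensus", reference="true")
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(pd.DataFrame(), "r1")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(tp=-1, fp=0, fn=1, tn=1)


class TestClopperPearson:
    def test_printed_interval_31_of_51(self):
        lo, hi = clopper_pearson(31, 51)
        assert (round(lo, 3), round(hi, 3)) == (0.461, 0.742)

    def test_printed_interval_11_of_16(self):
        lo, hi = clopper_pearson(11, 16)
        assert (round(lo, 3), round(hi, 3)) == (0.413, 0.890)

    def test_boundary_cases_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestDiagnosticMetrics:
    def test_perfect_table(self):
        m = diagnostic_metrics(ContingencyTable2x2(tp=30, fp=0, fn=0, tn=20))
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert est.point == 1.0
        assert m.lr_pos is None  # fp = 0: Simel CI non-computable

    def test_lr_flagged_not_computable_on_zero_denominators(self):
        m = diagnostic_metrics(ContingencyTable2x2(tp=10, fp=3, fn=0, tn=5))
        assert m.lr_neg is None  # fn = 0
        assert m.lr_pos is not None

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_bayes_consistency_exact_rational(self, counts):
        """PPV/NPV reproduce from sens, spec and prevalence via Bayes' rule."""
        tp, fp, fn, tn = counts
        m = diagnostic_metrics(ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn))
        sens = Fraction(tp, tp + fn)
        spec = Fraction(tn, tn + fp)
        prev = Fraction(tp + fn, tp + fp + fn + tn)
        ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        npv = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)
        assert m.ppv.point == pytest.approx(float(ppv), abs=1e-12)
        assert m.npv.point == pytest.approx(float(npv), abs=1e-12)
        assert m.prevalence == pytest.approx(float(prev), abs=1e-12)


class TestAssociation:
    def test_chi2_hand_computed_statistic(self):
        res = association_test(ContingencyTable2x2(tp=31, fp=5, fn=20, tn=11))
        assert res.name == "chi2"
        # n(ad-bc)^2 / (r1 r2 c1 c2)
        expected = 67 * (31 * 11 - 5 * 20) ** 2 / (36 * 31 * 51 * 16)
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(0.0387, abs=5e-4)

    def test_identical_row_proportions_give_p_one(self):
        res = association_test(ContingencyTable2x2(tp=10, fp=10, fn=20, tn=20))
        assert res.name == "chi2"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_low_expected_count_selects_fisher(self):
        res = association_test(ContingencyTable2x2(tp=15, fp=1, fn=36, tn=15))
        assert res.name == "fisher"  # expected cell 16*16/67 < 5

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            association_test(ContingencyTable2x2(tp=0, fp=0, fn=5, tn=5))
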