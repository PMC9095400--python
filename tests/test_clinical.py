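"""Clinical summary-table arithmetic and two-sample t comparisons."""

import numpy as np
import pytest

from usdenoise.clinical import (GroupComparison, OutcomeGroup,
                                complication_rate, load_group_tables,
                                summary_report, total_satisfaction,
                                two_sample_t)


@pytest.fixture(scope="module")
def groups():
    return load_group_tables()


class TestComplicationRate:
    def test_experimental_group_8_percent(self, groups):
        assert complication_rate(groups["experimental"]) == pytest.approx(8.0)

    def test_control_group_16_percent(self, groups):
        assert complication_rate(groups["control"]) == pytest.approx(16.0)

    def test_zero_counts(self):
        g = OutcomeGroup(label="g", n=50,
                         complication_counts={"bleeding": 0, "pain": 0})
        assert complication_rate(g) == 0.0

    def test_scale_free(self):
        g1 = OutcomeGroup(label="g", n=50, complication_counts={"a": 3, "b": 1})
        g2 = OutcomeGroup(label="g", n=100, complication_counts={"a": 6, "b": 2})
        assert complication_rate(g1) == complication_rate(g2)

    def test_counts_exceeding_n_rejected(self):
        g = OutcomeGroup(label="g", n=4, complication_counts={"a": 3, "b": 2})
        with pytest.raises(ValueError):
            complication_rate(g)


class TestTotalSatisfaction:
    def test_experimental_98_percent(self, groups):
        assert total_satisfaction(groups["experimental"]) == pytest.approx(98.0)

    def test_control_93_percent(self, groups):
        assert total_satisfaction(groups["control"]) == pytest.approx(93.0)

    def test_counts_form(self):
        g = OutcomeGroup(label="g", n=50, satisfaction={
            "very_satisfied": 0, "satisfied": 0, "dissatisfied": 50},
            satisfaction_as_percent=False)
        assert total_satisfaction(g) == 0.0
        g2 = OutcomeGroup(label="g", n=40, satisfaction={
            "very_satisfied": 10, "satisfied": 20, "dissatisfied": 10},
            satisfaction_as_percent=False)
        assert total_satisfaction(g2) == pytest.approx(75.0)

    def test_scale_free_counts(self):
        kw = dict(satisfaction_as_percent=False)
        g1 = OutcomeGroup("g", 10, satisfaction={"very_satisfied": 5,
                                                 "satisfied": 3,
                                                 "dissatisfied": 2}, **kw)
        g2 = OutcomeGroup("g", 20, satisfaction={"very_satisfied": 10,
                                                 "satisfied": 6,
                                                 "dissatisfied": 4}, **kw)
        assert total_satisfaction(g1) == total_satisfaction(g2)

    def test_bad_percentages_rejected(self):
        with pytest.raises(ValueError):
            OutcomeGroup("g", 50, satisfaction={"very_satisfied": 50,
                                                "satisfied": 20,
                                                "dissatisfied": 10})


class TestTwoSampleT:
    def test_identical_summaries_t0_p1(self):
        c = two_sample_t((5.0, 1.0, 30), (5.0, 1.0, 30))
        assert c.t_statistic == 0.0
        assert c.p_value == pytest.approx(1.0)

    def test_closed_form_pooled(self):
        # (0-1)/(1*sqrt(2/50)) = -5
        c = two_sample_t((0.0, 1.0, 50), (1.0, 1.0, 50), variant="pooled")
        assert c.t_statistic == pytest.approx(-5.0, abs=1e-9)
        assert c.df == 98

    def test_p_small_at_t5_df98(self):
        c = two_sample_t((0.0, 1.0, 50), (1.0, 1.0, 50))
        assert c.p_value < 0.05

    def test_antisymmetric_in_group_order(self):
        a, b = (3.2, 1.1, 40), (2.7, 0.9, 45)
        c1 = two_sample_t(a, b, variant="welch")
        c2 = two_sample_t(b, a, variant="welch")
        assert c1.t_statistic == pytest.approx(-c2.t_statistic)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_pooled_equals_welch_for_equal_sd_and_n(self):
        a, b = (3.0, 1.5, 25), (2.0, 1.5, 25)
        cp = two_sample_t(a, b, variant="pooled")
        cw = two_sample_t(a, b, variant="welch")
        assert cp.t_statistic == pytest.approx(cw.t_statistic, abs=1e-12)
        assert cp.p_value == pytest.approx(cw.p_value, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            two_sample_t((0, 0.0, 50), (1, 1.0, 50))
        with pytest.raises(ValueError):
            two_sample_t((0, 1.0, 1), (1, 1.0, 50))
        with pytest.raises(ValueError):
            two_sample_t((0, 1.0, 50), (1, 1.0, 50), variant="paired")
        with pytest.raises(ValueError):
            GroupComparison("x", {}, 0.0, 1.5, "pooled", 10)


class TestSummaryReport:
    def test_report_structure_and_known_values(self, groups):
        rep = summary_report(groups)
        assert rep["complication_rate_percent"]["experimental"] == 8.0
        assert rep["complication_rate_percent"]["control"] == 16.0
        assert rep["total_satisfaction_percent"]["experimental"] == 98.0
        assert rep["total_satisfaction_percent"]["control"] == 93.0
        assert "hospital_stay_days" in rep["comparisons"]
        for cmp in rep["comparisons"].values():
            assert 0.0 <= cmp["p"] <= 1.0

    def test_hospital_stay_significant(self, groups):
        rep = summary_report(groups)
        assert rep["comparisons"]["hospital_stay_days"]["p"] < 0.05

    def test_baseline_age_not_significant(self, groups):
        rep = summary_report(groups)
        assert rep["comparisons"]["age_years"]["p"] > 0.05
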