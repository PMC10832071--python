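"""Contingency/chi-square, summary t-test, and logistic regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonfh_collapse import (
    Cohort,
    ContingencyTable,
    SeparationError,
    build_contingency,
    fit_logistic,
    pearson_chi_square,
    t_test_from_summary,
)


def chi2_2x2_closed_form(a, b, c, d):
    """Classical (ad - bc)^2 N / (margin product) for a 2x2 table."""
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))


class TestContingency:
    def test_fixture_score_by_event(self, fixture_cohort):
        from nonfh_collapse import matrix_score

        table = build_contingency(
            fixture_cohort,
            lambda r: matrix_score(r.arco_stage, r.jic_type, r.area_category).value,
            "event",
        )
        assert table.row_labels == [1, 2, 4, 8]
        assert table.col_labels == [True, False]
        assert table.counts.tolist() == [[1, 24], [20, 42], [50, 35], [27, 3]]
        assert table.grand_total == 202

    def test_single_record_table_warns(self, fixture_cohort):
        one = Cohort([fixture_cohort.records[0]])
        with pytest.warns(UserWarning, match="single observed level"):
            table = build_contingency(one, "jic_type", "event")
        assert table.counts.tolist() == [[1]]

    def test_missing_value_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="missing value"):
            build_contingency(fixture_cohort, "sex", "event")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(np.array([[1, -1], [2, 3]]), ["a", "b"], ["x", "y"])


class TestPearsonChiSquare:
    def test_one_year_score_table(self):
        table = ContingencyTable(
            np.array([[1, 15, 31, 12], [24, 47, 54, 18]]),
            ["collapsed", "not"], [1, 2, 4, 8],
        )
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(12.295, abs=0.01)
        assert res.df == 3

    def test_sex_by_collapse_p_value(self):
        table = ContingencyTable(
            np.array([[71, 27], [70, 34]]), ["male", "female"], ["c", "nc"]
        )
        assert pearson_chi_square(table).p_value == pytest.approx(0.426, abs=0.002)

    def test_proportional_rows_give_zero(self):
        table = ContingencyTable(np.array([[10, 20], [5, 10]]), ["a", "b"], ["x", "y"])
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        table = ContingencyTable(np.array([[0, 0], [5, 10]]), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="zero row/column margin"):
            pearson_chi_square(table)

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_2x2_matches_closed_form(self, cells):
        a, b, c, d = cells
        table = ContingencyTable(np.array([[a, b], [c, d]]), ["r1", "r2"], ["c1", "c2"])
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(chi2_2x2_closed_form(a, b, c, d),
                                              rel=1e-10)

    @given(
        st.lists(st.integers(1, 30), min_size=6, max_size=6),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariance_under_permutation_and_transpose(self, cells, rnd):
        counts = np.array(cells).reshape(2, 3)
        base = pearson_chi_square(
            ContingencyTable(counts, ["a", "b"], ["x", "y", "z"])
        ).statistic
        perm = list(range(3))
        rnd.shuffle(perm)
        shuffled = counts[:, perm][::-1]
        assert pearson_chi_square(
            ContingencyTable(shuffled, ["b", "a"], ["?", "?", "?"])
        ).statistic == pytest.approx(base, rel=1e-12)
        assert pearson_chi_square(
            ContingencyTable(counts.T, ["x", "y", "z"], ["a", "b"])
        ).statistic == pytest.approx(base, rel=1e-12)


class TestSummaryTTest:
    def test_age_comparison(self):
        res = t_test_from_summary(52.48, 12.18, 98, 47.60, 12.57, 104)
        assert res.p_value == pytest.approx(0.006, abs=0.001)
        assert res.df == 200

    def test_bmi_comparison(self):
        res = t_test_from_summary(23.03, 2.76, 98, 22.90, 2.47, 104)
        assert res.p_value == pytest.approx(0.725, abs=0.005)

    def test_identical_groups(self):
        res = t_test_from_summary(10.0, 2.0, 50, 10.0, 2.0, 50)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            t_test_from_summary(1.0, 0.0, 10, 2.0, 1.0, 10)


class TestLogistic:
    def test_intercept_only_equals_event_logit(self, fixture_cohort):
        df = fixture_cohort.to_dataframe()
        fit = fit_logistic(df, "event", [])
        assert fit.coefficients[0] == pytest.approx(np.log(98 / 104), abs=1e-8)

    def test_binary_term_equals_2x2_log_odds(self, fixture_cohort):
        df = fixture_cohort.to_dataframe()
        df["score8"] = [1.0 if s == 8 else 0.0 for s in fixture_cohort.scores()]
        fit = fit_logistic(df, "event", ["score8"])
        expected = np.log((27 * 101) / (3 * 71))
        i = fit.term_labels.index("score8[1.0]")
        assert fit.coefficients[i] == pytest.approx(expected, abs=1e-6)

    def test_wald_and_ci_structure(self, fixture_cohort):
        df = fixture_cohort.to_dataframe()
        df["age_sim"] = np.linspace(30, 70, len(df))
        fit = fit_logistic(df, "event", ["age_sim", "arco_stage"],
                           reference_levels={"arco_stage": "I"})
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.coefficients))
        np.testing.assert_allclose(
            fit.ci_lower,
            np.exp(fit.coefficients - 1.96 * fit.standard_errors),
        )
        np.testing.assert_allclose(
            fit.wald_statistics,
            (fit.coefficients / fit.standard_errors) ** 2,
        )
        assert fit.reference_levels == {"arco_stage": "I"}
        assert fit.converged

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({
            "event": [0] * 20 + [1] * 20,
            "x": [0.0] * 20 + [1.0] * 20,
        })
        with pytest.raises(SeparationError):
            fit_logistic(df, "event", ["x"])

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.random(100)
        df = pd.DataFrame({
            "event": (rng.random(100) < 0.5).astype(float),
            "x1": x, "x2": 2.0 * x,
        })
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(df, "event", ["x1", "x2"])

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"event": [0.0, 0.5, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(df, "event", ["x"])
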