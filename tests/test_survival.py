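"""Kaplan-Meier product-limit curve and the k-group log-rank test.

The log-rank oracle below recomputes the statistic from first principles
(hypergeometric moments at each distinct event time) independently of the
implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonfh_collapse import km_estimate, log_rank


def logrank_oracle(groups):
    """Brute-force k-group log-rank statistic via hypergeometric moments."""
    times = [np.asarray(t, float) for t, _ in groups]
    events = [np.asarray(e, bool) for _, e in groups]
    k = len(groups)
    event_times = np.unique(np.concatenate(
        [t[e] for t, e in zip(times, events)]
    ))
    o_minus_e = np.zeros(k)
    v = np.zeros((k, k))
    for t in event_times:
        n_j = np.array([(tt >= t).sum() for tt in times], float)
        d_j = np.array([((tt == t) & ee).sum() for tt, ee in zip(times, events)],
                       float)
        n, d = n_j.sum(), d_j.sum()
        e_j = d * n_j / n
        o_minus_e += d_j - e_j
        if n > 1:
            factor = d * (n - d) / (n - 1.0)
            v += factor * (np.diag(n_j) * n - np.outer(n_j, n_j)) / n**2
    z = o_minus_e[:-1]
    return float(z @ np.linalg.solve(v[:-1, :-1], z))


class TestKaplanMeier:
    def test_fixture_survival_at_years(self, fixture_cohort):
        curve = km_estimate(fixture_cohort.times(), fixture_cohort.events())
        assert curve.survival_at(1) == pytest.approx(143 / 202)
        assert curve.survival_at(3) == pytest.approx(118 / 202)
        assert curve.survival_at(5) == pytest.approx(104 / 202)

    def test_fixture_median_not_reached(self, fixture_cohort):
        # 5-year survival is 51.5% > 50%: the product-limit median is
        # undefined within follow-up.
        curve = km_estimate(fixture_cohort.times(), fixture_cohort.events())
        assert curve.median is None

    def test_uncensored_quartet(self):
        curve = km_estimate([1, 2, 3, 4], [True] * 4)
        assert curve.survival_at(2) == pytest.approx(0.5)

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2 and 4:
        # S(1) = 3/4, S(3) = 3/4 * 1/2 = 0.375
        curve = km_estimate([1, 2, 3, 4], [True, False, True, False])
        assert curve.survival_at(3) == pytest.approx(0.375)
        assert curve.at_risk.tolist() == [4, 2]
        assert curve.events.tolist() == [1, 1]

    def test_bookkeeping_invariants(self, fixture_cohort):
        curve = km_estimate(fixture_cohort.times(), fixture_cohort.events())
        assert (np.diff(curve.event_times) > 0).all()
        assert (np.diff(curve.at_risk) < 0).all()
        assert (np.diff(curve.survival) <= 0).all()
        expected = np.cumprod(1 - curve.events / curve.at_risk)
        np.testing.assert_allclose(curve.survival, expected)

    @given(st.lists(st.integers(1, 40), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=40)
    def test_no_censoring_equals_empirical_survival(self, raw_times):
        times = np.array(raw_times, float) / 4.0
        curve = km_estimate(times, [True] * len(times))
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx(
                (times > t).mean(), abs=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        g = ([1.0, 2.0, 3.0, 4.0, 5.0], [True, True, False, True, False])
        res = log_rank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_matches_hypergeometric_oracle(self, rng, n_groups):
        for _ in range(20):
            groups = []
            for _ in range(n_groups):
                n = int(rng.integers(5, 25))
                times = rng.integers(1, 8, size=n).astype(float)
                events = rng.random(n) < 0.7
                if not events.any():
                    events[0] = True
                groups.append((times, events))
            res = log_rank(groups)
            assert res.statistic == pytest.approx(
                logrank_oracle(groups), rel=1e-6
            )
            assert res.df == n_groups - 1

    def test_relabeling_invariance(self, rng):
        groups = [
            (rng.exponential(3, 15) + 0.1, rng.random(15) < 0.8)
            for _ in range(3)
        ]
        base = log_rank(groups).statistic
        assert log_rank(groups[::-1]).statistic == pytest.approx(base, rel=1e-9)

    def test_two_group_statistic_is_squared_standardized_oe(self, rng):
        """For k=2 the statistic equals (O1-E1)^2 / Var(O1-E1)."""
        groups = [
            (rng.integers(1, 6, 20).astype(float), rng.random(20) < 0.7),
            (rng.integers(1, 6, 25).astype(float), rng.random(25) < 0.5),
        ]
        assert log_rank(groups).statistic == pytest.approx(
            logrank_oracle(groups), rel=1e-6
        )

    def test_fixture_by_score_is_highly_significant(self, fixture_cohort):
        scores = np.array(fixture_cohort.scores())
        times = np.array(fixture_cohort.times())
        events = np.array(fixture_cohort.events())
        groups = [(times[scores == s], events[scores == s]) for s in (1, 2, 4, 8)]
        res = log_rank(groups)
        assert res.statistic > 0
        assert res.p_value < 0.001

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            log_rank([([1.0, 2.0], [False, False]), ([1.5], [False])])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            log_rank([([1.0], [True])])
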