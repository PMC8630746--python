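import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from crss.survival import (
    concordance_index,
    fit_cox,
    group_tests,
    kaplan_meier,
    km_summary,
    logrank_test,
)


def _random_survival(rng, n, tie_free=False):
    times = rng.exponential(50, size=n) + 1
    if tie_free:
        times = np.sort(times) + np.arange(n) * 1e-6
        rng.shuffle(times)
    events = rng.integers(0, 2, size=n)
    return times, events


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = kaplan_meier([3, 5, 9], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert curve.survival_at(100) == 1.0
        assert curve.median is None

    def test_hand_computed_two_subjects(self):
        curve = kaplan_meier([5, 8], [1, 0])
        assert curve.survival_at(5) == pytest.approx(0.5)

    def test_hand_computed_with_tied_events(self):
        # Censor at 1, two deaths among three at risk at t=2: S(2) = 1/3.
        curve = kaplan_meier([1, 2, 2, 3], [0, 1, 1, 1])
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_count_conservation(self, rng):
        times, events = _random_survival(rng, 120)
        curve = kaplan_meier(times, events)
        removed = curve.n_events + curve.n_censored
        assert np.array_equal(curve.at_risk[1:], curve.at_risk[:-1] - removed[:-1])
        assert curve.at_risk[0] == 120

    def test_matches_lifelines(self, rng):
        times, events = _random_survival(rng, 200)
        curve = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [1, 10, 25, 60, 150]:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3, 6, 9, 12]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_no_censoring(self):
        # A events at {1, 2}, B events at {3, 4}: O_A=2, E_A=5/6, V=17/36.
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        expected = (2 - 5 / 6) ** 2 / (17 / 36)
        assert res.chi_square == pytest.approx(expected, rel=1e-12)
        assert res.df == 1

    def test_symmetric_in_group_labels(self, rng):
        ta, ea = _random_survival(rng, 40)
        tb, eb = _random_survival(rng, 55)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)

    def test_matches_lifelines_with_ties(self, rng):
        ta = rng.integers(1, 30, size=60).astype(float)
        ea = rng.integers(0, 2, size=60)
        tb = rng.integers(1, 30, size=45).astype(float)
        eb = rng.integers(0, 2, size=45)
        ours = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])


def _log_partial_likelihood(beta, times, events, x):
    """Breslow log partial likelihood for a single covariate, no tied times."""
    order = np.argsort(times)
    t, e, xv = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = xv[i:]  # all with time >= t_i
            ll += beta * xv[i] - np.log(np.sum(np.exp(beta * risk)))
    return ll


class TestCox:
    def _toy(self):
        times = np.array([2.0, 3.5, 5.0, 7.0, 11.0, 13.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        return times, events, x

    def test_coefficient_matches_grid_search(self):
        times, events, x = self._toy()
        grid = np.linspace(-5, 5, 100001)  # 1e-4 spacing
        lls = [_log_partial_likelihood(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        fit = fit_cox(times, events, x.reshape(-1, 1), names=["x"])
        assert fit.coefficients["x"] == pytest.approx(beta_star, abs=1e-4)
        assert fit.hazard_ratios["x"] == pytest.approx(np.exp(beta_star), abs=1e-3)

    def test_information_criteria_identities(self):
        times, events, x = self._toy()
        fit = fit_cox(times, events, x.reshape(-1, 1), names=["x"])
        assert fit.aic == pytest.approx(-2 * fit.log_partial_likelihood + 2)
        assert fit.bic == pytest.approx(
            -2 * fit.log_partial_likelihood + np.log(fit.n_events)
        )
        assert fit.ci_lower["x"] <= fit.hazard_ratios["x"] <= fit.ci_upper["x"]

    def test_constant_covariate_named_in_error(self):
        times, events, _ = self._toy()
        with pytest.raises(ValueError, match="flat"):
            fit_cox(times, events, np.ones((6, 1)), names=["flat"])

    def test_time_scale_invariance(self):
        times, events, x = self._toy()
        f1 = fit_cox(times, events, x.reshape(-1, 1), names=["x"])
        f2 = fit_cox(times * 2, events, x.reshape(-1, 1), names=["x"])
        assert f1.coefficients["x"] == pytest.approx(f2.coefficients["x"], rel=1e-6)

    def test_local_maximum_of_partial_likelihood(self, rng):
        n = 50
        x = rng.normal(size=n)
        times = rng.exponential(scale=np.exp(-0.8 * x)) + 1e-3
        times += np.arange(n) * 1e-9  # break ties
        events = np.ones(n, dtype=int)
        fit = fit_cox(times, events, x.reshape(-1, 1), names=["x"])
        beta_hat = fit.coefficients["x"]
        best = _log_partial_likelihood(beta_hat, times, events, x)
        for _ in range(100):
            near = beta_hat + rng.uniform(-0.2, 0.2)
            assert _log_partial_likelihood(near, times, events, x) <= best + 1e-8


def _cindex_bruteforce(times, events, risk):
    conc = disc = ties = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] < risk[j]:
                    disc += 1
                else:
                    ties += 1
    total = conc + disc + ties
    return (conc + 0.5 * ties) / total


class TestConcordance:
    def test_perfect_ordering(self):
        times = [1, 2, 3, 4]
        events = [1, 1, 1, 1]
        assert concordance_index(times, events, [4, 3, 2, 1]) == 1.0

    def test_constant_scores_are_chance(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5

    def test_mixed_censoring_matches_bruteforce(self):
        times = [2.0, 4.0, 5.0, 7.0, 9.0]
        events = [1, 0, 1, 1, 0]
        risk = [3.0, 1.0, 2.5, 2.5, 0.5]
        assert concordance_index(times, events, risk) == pytest.approx(
            _cindex_bruteforce(times, events, risk), abs=1e-12
        )

    def test_random_data_matches_bruteforce(self, rng):
        times, events = _random_survival(rng, 50, tie_free=True)
        risk = np.round(rng.normal(size=50), 1)  # induce score ties
        assert concordance_index(times, events, risk) == pytest.approx(
            _cindex_bruteforce(times, events, risk), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        times, events = _random_survival(rng, 60, tie_free=True)
        risk = rng.normal(size=60)
        c1 = concordance_index(times, events, risk)
        c2 = concordance_index(times, events, np.exp(3 * risk) + 7)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([5, 5], [0, 0], [1, 2])


class TestKmSummary:
    def test_flat_curve(self):
        curve = kaplan_meier([10, 20], [0, 0])
        summ = km_summary(curve)
        assert all(summ[f"year_{y}"] == 1.0 for y in range(1, 6))
        assert summ["median_weeks"] is None

    def test_median_at_half_step(self):
        curve = kaplan_meier([5.0, 6.0], [1, 0])
        assert curve.median == 5.0

    def test_between_steps_uses_left_value(self):
        curve = kaplan_meier([10.0, 100.0], [1, 1])
        # At 52.18 weeks (year 1) the last step was at t=10 (S=0.5).
        assert km_summary(curve, horizons_years=[1])["year_1"] == pytest.approx(0.5)


class TestGroupTests:
    def test_identical_groups_are_null(self):
        res = group_tests([[1, 2, 3], [1, 2, 3]])
        assert res.kruskal_p == pytest.approx(1.0)
        assert res.pairwise_p[0] == pytest.approx(1.0)

    def test_separated_groups_match_exact_enumeration(self):
        # Perfect separation of 3 vs 3: exact two-sided rank-sum p = 2/C(6,3).
        res = group_tests([[1, 2, 3], [11, 12, 13]])
        assert res.pairwise_p[0] == pytest.approx(2 / 20)

    def test_kruskal_invariant_to_group_order(self, rng):
        groups = [rng.normal(size=12), rng.normal(1, 1, size=9), rng.normal(2, 1, size=15)]
        p1 = group_tests(groups).kruskal_p
        p2 = group_tests(groups[::-1]).kruskal_p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_tests([[1, 2], []])
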