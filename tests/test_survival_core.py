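"""Survival stack vs independent oracles: hand tabulations, grid search, lifelines."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank
import pandas as pd

import panelscan as ps
from panelscan.survival_core import SurvivalError

from conftest import spawn_seeds


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = ps.km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        # 3/4, then x 2/3, censor at 3, then x 0/1
        assert [km.survival_at(t) for t in (1, 2, 3, 4)] == \
            pytest.approx([0.75, 0.50, 0.50, 0.0])

    def test_all_censored_flat_one(self):
        km = ps.km_estimate([5, 8, 13], [0, 0, 0])
        assert all(km.survival_at(t) == 1.0 for t in (0, 5, 13, 99))

    def test_duplication_invariance(self):
        t = [2.0, 4.0, 4.0, 7.0, 9.0]
        e = [1, 0, 1, 1, 0]
        a = ps.km_estimate(t, e)
        b = ps.km_estimate(t * 2, e * 2)
        np.testing.assert_allclose(a.survival, b.survival)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 50)
        km = ps.km_estimate(t, np.ones(50))
        for u in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(u) == pytest.approx(np.mean(t > u))

    def test_at_risk_strictly_decreasing(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80).round(0) + 1
        e = rng.integers(0, 2, 80)
        km = ps.km_estimate(t, e)
        assert np.all(np.diff(km.at_risk) < 0)
        assert np.all(np.diff(km.survival) <= 0)

    @pytest.mark.parametrize("t,e,err", [
        ([], [], "empty"),
        ([-1.0], [1], "negative"),
        ([1.0], [2], "0 or 1"),
        ([0.0], [1], "time 0"),
    ])
    def test_invalid_inputs(self, t, e, err):
        with pytest.raises(SurvivalError, match=err):
            ps.km_estimate(t, e)


def brute_force_logrank(times, events, in_g1):
    """Independent per-event-time 2x2 tabulation (plain Python loops)."""
    times = list(map(float, times))
    o1 = e1 = v = o_tot = 0.0
    for u in sorted({t for t, ev in zip(times, events) if ev == 1}):
        at = [(t, ev, g) for t, ev, g in zip(times, events, in_g1) if t >= u]
        n = len(at)
        n1 = sum(1 for _, _, g in at if g)
        d = sum(1 for t, ev, _ in at if t == u and ev == 1)
        d1 = sum(1 for t, ev, g in at if t == u and ev == 1 and g)
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o_tot += d
    return o1, e1, v, o_tot


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        res = ps.logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0)
        assert res.hr == pytest.approx(1.0)

    def test_six_subject_fixture_matches_tabulation_oracle(self):
        t = [6.0, 7.0, 10.0, 15.0, 19.0, 25.0]
        e = [1, 0, 1, 1, 0, 1]
        g1 = [True, True, True, False, False, False]
        o1, e1, v, o_tot = brute_force_logrank(t, e, g1)
        res = ps.logrank_test(t, e, np.where(g1, "x", "y"), ("x", "y"))
        assert res.observed[0] == pytest.approx(o1)
        assert res.expected[0] == pytest.approx(e1)
        assert res.variance == pytest.approx(v)
        assert sum(res.observed) == pytest.approx(o_tot)
        assert res.chi2 == pytest.approx((o1 - e1) ** 2 / v)

    def test_random_data_matches_oracle_and_lifelines(self):
        rng = np.random.default_rng(44)
        t = (rng.exponential(20, 60).round(0) + 1)
        e = rng.integers(0, 2, 60)
        g1 = rng.random(60) < 0.5
        e[:2] = 1  # ensure events exist
        o1, e1, v, _ = brute_force_logrank(t, e, g1)
        res = ps.logrank_test(t, e, np.where(g1, "x", "y"), ("x", "y"))
        assert res.chi2 == pytest.approx((o1 - e1) ** 2 / v)
        ll = ll_logrank(t[g1], t[~g1], e[g1], e[~g1])
        assert res.chi2 == pytest.approx(ll.test_statistic)
        assert res.p == pytest.approx(ll.p_value)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(20, 100)
        e = rng.integers(0, 2, 100)
        g = np.where(rng.random(100) < 0.5, "x", "y")
        a = ps.logrank_test(t, e, g, ("x", "y"))
        b = ps.logrank_test(t, e, g, ("y", "x"))
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.hr == pytest.approx(1.0 / b.hr)

    def test_permutation_null_rejection_rate(self):
        rng = np.random.default_rng(1234)
        t = rng.exponential(15, 80)
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        n_rep, rej = 1000, 0
        for _ in range(n_rep):
            g = np.where(rng.permutation(80) < 40, "x", "y")
            rej += ps.logrank_test(t, e, g, ("x", "y")).p < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half <= rej / n_rep <= 0.05 + half

    def test_degenerate_inputs(self):
        with pytest.raises(SurvivalError, match="2 groups"):
            ps.logrank_test([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(SurvivalError, match="no events"):
            ps.logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_cox_hr_option(self):
        rng = np.random.default_rng(2)
        g1 = rng.random(200) < 0.5
        t = rng.exponential(np.where(g1, 5, 10))
        res = ps.logrank_test(t, np.ones(200), np.where(g1, "x", "y"),
                              ("x", "y"), hr_method="cox")
        assert 1.5 < res.hr < 2.7   # true HR 2


def independent_partial_loglik(beta, times, events, x):
    """No-ties partial likelihood written from the definition (test oracle)."""
    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if ei == 1:
            risk = [j for j, tj in enumerate(times) if tj >= ti]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_eight_subject_fixture_vs_grid_search(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        e = [1, 0, 1, 1, 0, 1, 1, 0]
        x = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0]
        fit = ps.cox_fit(t, e, np.array(x)[:, None], names=["g"])
        grid = np.linspace(-4, 4, 8001)
        lls = [independent_partial_loglik(b, t, e, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        fine = np.linspace(best - 1e-3, best + 1e-3, 2001)
        lls = [independent_partial_loglik(b, t, e, x) for b in fine]
        best = fine[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(250, 3))
        beta = np.array([0.5, -0.3, 0.8])
        t0 = rng.exponential(1 / (0.01 * np.exp(X @ beta)))
        c = rng.uniform(0, 150, 250)
        t = np.minimum(t0, c).round(0) + 1          # heavy ties
        e = (t0 <= c).astype(float)
        for ties in ("efron", "breslow"):
            fit = ps.cox_fit(t, e, X, names=list("abc"), ties_method=ties)
            df = pd.DataFrame(X, columns=list("abc"))
            df["T"], df["E"] = t, e
            cph = CoxPHFitter().fit(df, "T", "E")
            if ties == "efron":   # lifelines implements Efron only
                np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-4)
                np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                           atol=1e-4)
                assert fit.log_likelihood == pytest.approx(cph.log_likelihood_,
                                                           abs=1e-5)
            assert fit.converged

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(10, 100)            # continuous -> no ties
        e = rng.integers(0, 2, 100).astype(float)
        e[:3] = 1
        X = rng.normal(size=(100, 2))
        fe = ps.cox_fit(t, e, X, ties_method="efron")
        fb = ps.cox_fit(t, e, X, ties_method="breslow")
        np.testing.assert_allclose(fe.coef, fb.coef, rtol=1e-8)
        assert fe.log_likelihood == pytest.approx(fb.log_likelihood)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 2000)
        x = rng.normal(size=(2000, 1))
        fit = ps.cox_fit(t, np.ones(2000), x, names=["noise"])
        assert abs(fit.coef[0]) < 0.1
        assert fit.wald_p[0] > 0.001

    def test_true_hr_two_recovery(self):
        rng = np.random.default_rng(15)
        g = (rng.random(2000) < 0.5).astype(float)
        t = rng.exponential(1 / (0.01 * 2.0 ** g))
        fit = ps.cox_fit(t, np.ones(2000), g[:, None], names=["g"])
        assert 1.85 < fit.hr[0] < 2.15

    def test_wald_matches_logrank_first_order(self):
        rng = np.random.default_rng(77)
        g = (rng.random(1500) < 0.5)
        t = rng.exponential(np.where(g, 8.0, 10.0))
        e = np.ones(1500)
        fit = ps.cox_fit(t, e, g.astype(float)[:, None])
        wald_chi2 = (fit.coef[0] / fit.se[0]) ** 2
        lr = ps.logrank_test(t, e, np.where(g, "x", "y"), ("x", "y"))
        assert wald_chi2 == pytest.approx(lr.chi2, rel=0.05)

    def test_constant_covariate_named_in_error(self):
        t = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(SurvivalError, match="flat_cov"):
            ps.cox_fit(t, [1, 1, 0, 1], np.ones((4, 1)), names=["flat_cov"])

    def test_separation_flagged_not_converged(self):
        # perfect separation: all events in one group before any in the other
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        e = np.ones(8)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])[:, None]
        fit = ps.cox_fit(t, e, x)
        assert not fit.converged
        assert fit.message

    def test_ci_brackets_hr(self, small_cohort):
        expr, clin, gt = small_cohort
        t, e, ids = clin.survival("os")
        fit = ps.cox_fit(t, e, gt.scores.loc[ids].to_numpy()[:, None],
                         names=["score"])
        lo, hi = fit.ci95[0]
        assert lo < fit.hr[0] < hi
        np.testing.assert_allclose(
            [lo, hi], np.exp(fit.coef[0] + np.array([-1, 1]) * 1.959964 * fit.se[0]),
            rtol=1e-6)
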