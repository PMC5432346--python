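"""Survival primitives against brute-force oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cvasd
from cvasd.errors import (
    CollinearityError,
    ConvergenceWarning,
    DataValidationError,
    MonotoneLikelihoodWarning,
)

from oracles import (
    cox_brute_force_1d,
    cox_partial_loglik_1d,
    fisher_two_sided_by_enumeration,
    km_by_hand,
    logrank_by_hand,
)


def _random_instance(rng, n):
    """A small untied single-covariate survival dataset with interior MLE."""
    while True:
        x = rng.standard_normal(n)
        beta = rng.normal(0, 0.8)
        t = rng.exponential(1.0 / np.exp(beta * x))
        if len(np.unique(t)) < n:
            continue
        event = (rng.random(n) < 0.8).astype(int)
        if event.sum() < 2:
            continue
        bhat = cox_brute_force_1d(t, event, x)
        if abs(bhat) < 6:
            return t, event, x, bhat


class TestCoxFit:
    def test_matches_brute_force_on_small_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            t, event, x, oracle_beta = _random_instance(rng, n)
            fit = cvasd.fit_cox(t, event, x[:, None], ties="breslow")
            assert fit.converged
            assert fit.coef[0] == pytest.approx(oracle_beta, abs=1e-3)

    def test_loglik_is_local_maximum(self, rng):
        t, event, x, _ = _random_instance(rng, 7)
        fit = cvasd.fit_cox(t, event, x[:, None], ties="breslow")
        at_opt = cox_partial_loglik_1d(fit.coef[0], t, event, x)
        assert at_opt == pytest.approx(fit.loglik, abs=1e-8)
        for probe in rng.normal(fit.coef[0], 1.0, size=25):
            assert cox_partial_loglik_1d(probe, t, event, x) <= at_opt + 1e-10

    def test_efron_equals_breslow_without_ties(self, rng):
        t, event, x, _ = _random_instance(rng, 8)
        fe = cvasd.fit_cox(t, event, x[:, None], ties="efron")
        fb = cvasd.fit_cox(t, event, x[:, None], ties="breslow")
        np.testing.assert_allclose(fe.coef, fb.coef, atol=1e-10)
        np.testing.assert_allclose(fe.loglik, fb.loglik, atol=1e-10)

    def test_matches_lifelines_with_ties(self):
        """Independent cross-check incl. tied event times (Efron)."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 120
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = np.ceil(rng.exponential(np.exp(-(0.5 * x1 - 0.3 * x2))) * 8)
        event = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame({"t": t, "e": event, "x1": x1, "x2": x2})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        fit = cvasd.fit_cox(t, event, df[["x1", "x2"]], ties="efron")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_degenerate_column_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        with pytest.warns(ConvergenceWarning):
            fit = cvasd.fit_cox(t, e, np.zeros((4, 1)))
        assert fit.flagged
        assert fit.coef[0] == 0.0
        assert fit.wald_p[0] == 1.0

    def test_monotone_likelihood_warns(self):
        t = np.array([1.0, 2.0])
        e = np.array([1, 1])
        x = np.array([[1.0], [0.0]])
        with pytest.warns(MonotoneLikelihoodWarning):
            fit = cvasd.fit_cox(t, e, x)
        assert not fit.converged

    def test_zero_events_error(self):
        with pytest.raises(DataValidationError):
            cvasd.fit_cox([1.0, 2.0], [0, 0], np.ones((2, 1)))

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        t = rng.exponential(1, 20) + 0.01
        e = np.ones(20, dtype=int)
        with pytest.raises(CollinearityError):
            cvasd.fit_cox(t, e, np.column_stack([x, 2 * x]))

    def test_invariants(self, rng):
        t, event, x, _ = _random_instance(rng, 8)
        fit = cvasd.fit_cox(t, event, x[:, None])
        np.testing.assert_allclose(fit.hr, np.exp(fit.coef))
        ci = fit.hr_ci
        assert np.all(ci[:, 0] <= fit.hr) and np.all(fit.hr <= ci[:, 1])
        assert np.all((fit.wald_p > 0) & (fit.wald_p <= 1))
        assert np.isfinite(fit.loglik)


class TestSingleGeneInteraction:
    def test_recovers_planted_interaction_when_sole_gene(self):
        cfg = cvasd.SimulationConfig(
            n_patients=400, n_genes=5, n_sensitive_genes=1,
            i_true=-1.5, sensitive_fraction_target=None,
            censoring_rate=0.3, treatment_prob=0.5, seed=42,
        )
        c = cvasd.simulate(cfg)
        co = c.data.cohort
        f = cvasd.fit_single_gene_interaction(
            co.time, co.event, co.treatment, c.data.expression.values[:, 0]
        )
        assert f.converged
        assert abs(f.i_hat - (-1.5)) < 3 * f.se_i

    def test_null_interaction_p_uniform(self):
        """Wald p of the interaction is ~U(0,1) under the null."""
        from scipy import stats

        rng = np.random.default_rng(100)
        pvals = []
        for _ in range(200):
            n = 200
            r = (rng.random(n) < 0.5).astype(int)
            x = rng.standard_normal(n)
            t = rng.exponential(1.0, n)
            e = (rng.random(n) < 0.7).astype(int)
            if e[r == 1].sum() == 0 or e[r == 0].sum() == 0:
                continue
            pvals.append(
                cvasd.fit_single_gene_interaction(t, e, r, x).p_interaction
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_expression_flagged(self):
        rng = np.random.default_rng(1)
        n = 30
        t = rng.exponential(1, n) + 0.01
        e = np.ones(n, dtype=int)
        r = np.arange(n) % 2
        with pytest.warns(ConvergenceWarning):
            f = cvasd.fit_single_gene_interaction(t, e, r, np.zeros(n))
        assert f.flagged and f.p_interaction == 1.0

    def test_single_arm_events_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0])
        r = np.array([1, 1, 0, 0])
        with pytest.raises(DataValidationError):
            cvasd.fit_single_gene_interaction(t, e, r, np.array([0.1, 0.2, 0.3, 0.4]))


class TestLogRank:
    def test_micro_fixture_matches_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        g = np.array(["A", "A", "B", "B"])
        res = cvasd.logrank(t, e, g)
        ome, var, chi2 = logrank_by_hand(t, e, g)
        assert ome == pytest.approx(2 - (2 / 4 + 1 / 3 + 0 + 0), abs=1e-12)
        obs_minus_exp = res.observed[0] - res.expected[0]
        assert obs_minus_exp == pytest.approx(ome, abs=1e-10)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.expected.sum() == pytest.approx(res.observed.sum(), abs=1e-8)

    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 5.0, 1.0, 2.0, 5.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = cvasd.logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_relabeling_invariance_and_chi2_of_score(self, rng):
        n = 40
        t = rng.exponential(1, n) + 0.01
        e = (rng.random(n) < 0.7).astype(int)
        g = (rng.random(n) < 0.5).astype(int)
        if e.sum() == 0 or len(np.unique(g)) < 2:
            pytest.skip("degenerate draw")
        r1 = cvasd.logrank(t, e, g)
        r2 = cvasd.logrank(t, e, 1 - g)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        ome, var, chi2 = logrank_by_hand(t, e, g)
        assert r1.statistic == pytest.approx(chi2, rel=1e-8)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(8)
        n = 100
        t = np.ceil(rng.exponential(5, n)) + 1
        e = (rng.random(n) < 0.6).astype(int)
        g = (rng.random(n) < 0.4).astype(int)
        res = cvasd.logrank(t, e, g)
        ll = lifelines_stats.logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ll.p_value, rel=1e-8)

    def test_three_groups_df(self, rng):
        n = 60
        t = rng.exponential(1, n) + 0.01
        e = np.ones(n, dtype=int)
        g = rng.integers(0, 3, n)
        res = cvasd.logrank(t, e, g)
        assert res.df == 2
        assert res.statistic >= 0

    def test_errors(self):
        with pytest.raises(DataValidationError):
            cvasd.logrank([1.0, 2.0], [1, 1], ["A", "A"])
        with pytest.raises(DataValidationError):
            cvasd.logrank([1.0, 2.0], [0, 0], ["A", "B"])


class TestKaplanMeier:
    def test_hand_fixture(self):
        res = cvasd.km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(res.times, [1.0, 3.0])
        np.testing.assert_allclose(res.surv, [2 / 3, 0.0])
        assert res.at(2.0) == pytest.approx(2 / 3)

    def test_all_censored_is_unity(self):
        res = cvasd.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert res.times.size == 0
        assert res.at(10.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50) + 0.01
        res = cvasd.km_curve(t, np.ones(50))
        ot, os_ = km_by_hand(t, np.ones(50, int))
        np.testing.assert_allclose(res.times, ot)
        np.testing.assert_allclose(res.surv, os_, atol=1e-12)
        for tt, ss in zip(res.times, res.surv):
            assert ss == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_band_properties(self, rng):
        t = rng.exponential(1, 80) + 0.01
        e = (rng.random(80) < 0.6).astype(int)
        if e.sum() == 0:
            pytest.skip("no events")
        res = cvasd.km_curve(t, e)
        assert np.all(np.diff(res.surv) <= 1e-12)
        assert np.all((res.surv >= 0) & (res.surv <= 1))
        assert np.all(res.lower <= res.surv + 1e-12)
        assert np.all(res.upper >= res.surv - 1e-12)
        assert np.all((res.lower >= 0) & (res.upper <= 1))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[0, 4], [4, 0]], 2 / 70),
        ],
    )
    def test_enumeration_fixtures(self, table, expected):
        assert cvasd.fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)

    def test_independence_table_gives_one(self):
        assert cvasd.fisher_exact_2x2([[2, 4], [3, 6]]) == pytest.approx(1.0)

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    def test_matches_enumeration(self, a, b, c, d):
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            with pytest.raises(DataValidationError):
                cvasd.fisher_exact_2x2(table)
            return
        assert cvasd.fisher_exact_2x2(table) == pytest.approx(
            fisher_two_sided_by_enumeration(table), rel=1e-10
        )

    def test_validation(self):
        with pytest.raises(DataValidationError):
            cvasd.fisher_exact_2x2([[1, -1], [2, 2]])
        with pytest.raises(DataValidationError):
            cvasd.fisher_exact_2x2([[1.5, 1], [2, 2]])
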