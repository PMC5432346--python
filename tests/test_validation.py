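"""Four-subgroup analysis, adjusted Cox panels, strata, outcome rates, clustering."""

import numpy as np
import pandas as pd
import pytest

import cvasd
from cvasd.errors import CollinearityError, DataValidationError
from cvasd.validation import CONTRASTS, SUBGROUPS


@pytest.fixture(scope="module")
def cohort_and_calls():
    c = cvasd.simulate(cvasd.SimulationConfig(
        n_patients=160, n_genes=20, n_sensitive_genes=5, seed=17,
        censoring_rate=0.4, treatment_prob=0.5,
    ))
    calls = c.truth["sensitive_true"].to_numpy().astype(bool)
    return c, calls


class TestFourSubgroups:
    def test_partition_and_sizes(self, cohort_and_calls):
        c, calls = cohort_and_calls
        res = cvasd.four_subgroup_analysis(c.data.cohort, calls)
        assert sum(res.sizes.values()) == c.data.n
        assert set(res.sizes) == set(SUBGROUPS)
        assert set(res.contrasts) == set(CONTRASTS)

    def test_all_sensitive_reduces_to_unconditional_treatment_test(
        self, cohort_and_calls
    ):
        c, _ = cohort_and_calls
        cohort = c.data.cohort
        with pytest.warns(UserWarning):
            res = cvasd.four_subgroup_analysis(cohort, np.ones(cohort.n, bool))
        ref = cvasd.logrank(cohort.time, cohort.event, cohort.treatment)
        t = res.contrasts["RS: RT vs no-RT"]
        assert t.statistic == ref.statistic and t.p == ref.p
        assert res.contrasts["NRS: RT vs no-RT"] is None
        assert res.contrasts["RT: RS vs NRS"] is None

    def test_calls_dataframe_accepted(self, cohort_and_calls):
        c, calls = cohort_and_calls
        df = pd.DataFrame(
            {"patient_id": c.data.cohort.patient_ids, "sensitive": calls.astype(int)}
        ).sample(frac=1.0, random_state=0)  # shuffled: must align by id
        res_a = cvasd.four_subgroup_analysis(c.data.cohort, df)
        res_b = cvasd.four_subgroup_analysis(c.data.cohort, calls)
        for name in CONTRASTS:
            assert res_a.contrasts[name].p == res_b.contrasts[name].p

    def test_benefit_visible_in_true_sensitive_group(self, cohort_and_calls):
        """Planted i=-1.5: treated truly-sensitive patients survive longer."""
        c, calls = cohort_and_calls
        res = cvasd.four_subgroup_analysis(c.data.cohort, calls)
        t = res.contrasts["RS: RT vs no-RT"]
        assert t is not None and t.p < 0.05


class TestAdjustedCox:
    def test_no_covariates_equals_unadjusted(self, cohort_and_calls):
        c, calls = cohort_and_calls
        cohort = c.data.cohort
        effects = cvasd.adjusted_cox(cohort, calls, covariates=[])
        rs = calls
        sub_t = cohort.time[rs]
        sub_e = cohort.event[rs]
        sub_r = cohort.treatment[rs]
        ref = cvasd.fit_cox(sub_t, sub_e, sub_r[:, None].astype(float))
        eff = next(e for e in effects if e.contrast == "RT vs no-RT | RS")
        assert eff.hr == pytest.approx(float(ref.hr[0]), rel=1e-10)
        assert eff.wald_p == pytest.approx(float(ref.wald_p[0]), rel=1e-10)

    def test_adjusts_for_categorical_and_numeric(self, cohort_and_calls):
        c, calls = cohort_and_calls
        effects = cvasd.adjusted_cox(
            c.data.cohort, calls, covariates=["age", "gender", "histology"]
        )
        assert len(effects) == 4
        for e in effects:
            assert e.ci95[0] <= e.hr <= e.ci95[1]
            assert 0 < e.wald_p <= 1

    def test_covariate_equal_to_contrast_raises(self, cohort_and_calls):
        c, calls = cohort_and_calls
        cohort = c.data.cohort
        df = cohort.df.copy()
        df["rt_copy"] = df["treatment"].astype(float)
        twin = cvasd.SurvivalCohort(df=df, covariates=["rt_copy"])
        with pytest.raises(CollinearityError):
            cvasd.adjusted_cox(twin, calls, covariates=["rt_copy"])

    def test_harmful_treatment_in_nonsensitive_stratum_detected(self):
        """Planted lambda > 0 with negative interactions: treatment harms the
        nonsensitive stratum (HR > 1) while benefiting sensitive patients."""
        hits = 0
        for seed in range(5):
            c = cvasd.simulate(cvasd.SimulationConfig(
                n_patients=250, n_genes=10, n_sensitive_genes=5,
                lambda_true=0.6, i_true=-2.0, seed=seed,
                censoring_rate=0.4, treatment_prob=0.5,
            ))
            calls = c.truth["sensitive_true"].to_numpy().astype(bool)
            effects = cvasd.adjusted_cox(c.data.cohort, calls, covariates=[])
            nrs = next(e for e in effects if e.contrast == "RT vs no-RT | NRS")
            hits += nrs.hr > 1
        assert hits >= 4


class TestStrata:
    def test_single_level_matches_four_subgroup(self, cohort_and_calls):
        c, calls = cohort_and_calls
        cohort = c.data.cohort
        df = cohort.df.copy()
        df["site"] = "only"
        one = cvasd.SurvivalCohort(df=df, covariates=["site"])
        strata = cvasd.strata_analysis(one, calls, stratum="site", min_size=1)
        assert list(strata) == ["only"]
        full = cvasd.four_subgroup_analysis(cohort, calls)
        for name in CONTRASTS:
            a, b = strata["only"].contrasts[name], full.contrasts[name]
            assert (a is None) == (b is None)
            if a is not None:
                assert a.p == b.p

    def test_small_levels_merged_into_other(self, cohort_and_calls):
        c, calls = cohort_and_calls
        strata = cvasd.strata_analysis(
            c.data.cohort, calls, stratum="histology", min_size=40
        )
        counts = c.data.cohort.df["histology"].value_counts()
        expected = {lvl for lvl, n in counts.items() if n >= 40} | {"other"}
        assert set(strata) == expected

    def test_benefit_direction_consistent_across_strata(self, cohort_and_calls):
        """Sensitivity was planted independent of histology, so the RS
        treatment-benefit contrast points the same way in every stratum."""
        c, calls = cohort_and_calls
        strata = cvasd.strata_analysis(
            c.data.cohort, calls, stratum="histology", min_size=30
        )
        for res in strata.values():
            t = res.contrasts["RS: RT vs no-RT"]
            if t is None:
                continue
            # fewer observed than expected deaths among treated sensitive
            idx = list(t.groups).index(1)
            assert t.observed[idx] <= t.expected[idx] + 1e-9


class TestOutcomeRates:
    def test_wired_through_fisher(self, cohort_and_calls):
        c, calls = cohort_and_calls
        cohort = c.data.cohort
        rng = np.random.default_rng(2)
        outcome = (rng.random(cohort.n) < 0.3).astype(float)
        res = cvasd.outcome_rate_tests(cohort, calls, outcome)
        assert set(res) == set(CONTRASTS)
        for name, (table, p) in res.items():
            if p is None:
                continue
            assert p == pytest.approx(cvasd.fisher_exact_2x2(table), abs=1e-12)

    def test_constant_outcome_gives_undefined(self, cohort_and_calls):
        c, calls = cohort_and_calls
        with pytest.warns(UserWarning, match="zero-margin"):
            res = cvasd.outcome_rate_tests(c.data.cohort, calls,
                                           np.zeros(c.data.n))
        assert all(p is None for _, p in res.values())

    def test_missing_excluded_pairwise(self, cohort_and_calls):
        c, calls = cohort_and_calls
        rng = np.random.default_rng(3)
        outcome = (rng.random(c.data.n) < 0.4).astype(float)
        outcome[:10] = np.nan
        res = cvasd.outcome_rate_tests(c.data.cohort, calls, outcome)
        total = sum(res[name][0].sum() for name in CONTRASTS)
        # each patient enters exactly two contrasts
        assert total == 2 * (c.data.n - 10)


class TestClusterConcordance:
    def test_separated_blobs_give_unity(self):
        rng = np.random.default_rng(4)
        X = np.vstack([
            rng.normal(-5, 0.3, size=(20, 6)),
            rng.normal(+5, 0.3, size=(25, 6)),
        ])
        calls = np.array([True] * 20 + [False] * 25)
        res = cvasd.cluster_concordance(X, calls)
        assert res.concordance == 1.0

    def test_invariant_to_label_flip_and_patient_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 5))
        calls = rng.random(40) < 0.5
        a = cvasd.cluster_concordance(X, calls)
        b = cvasd.cluster_concordance(X, ~calls)
        assert a.concordance == pytest.approx(b.concordance)
        perm = rng.permutation(40)
        c = cvasd.cluster_concordance(X[perm], calls[perm])
        assert c.concordance == pytest.approx(a.concordance)

    def test_random_calls_near_half(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(30):
            X = rng.standard_normal((60, 4))
            calls = rng.random(60) < 0.5
            vals.append(cvasd.cluster_concordance(X, calls).concordance)
        assert 0.5 <= np.mean(vals) < 0.65

    def test_identical_rows_rejected(self):
        with pytest.raises(DataValidationError, match="identical"):
            cvasd.cluster_concordance(np.ones((5, 3)), np.ones(5, bool))

    def test_contrast_reuse_is_structural(self, cohort_and_calls):
        """The four contrasts are LogRankResult objects from the shared
        primitive, not a parallel statistic implementation."""
        c, calls = cohort_and_calls
        res = cvasd.four_subgroup_analysis(c.data.cohort, calls)
        for t in res.contrasts.values():
            if t is not None:
                assert isinstance(t, cvasd.LogRankResult)
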