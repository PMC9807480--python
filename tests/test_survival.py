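import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mbrisk import cox as mcox
from mbrisk.survival import (build_td_dataset, censoring_km, cohens_kappa,
                             concordance_on_rows, cox_fit, km_estimate,
                             logrank_test, pearson_chisq)


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert km.survival_at(2.5) == pytest.approx(1 / 3)
        assert km.survival_at(0.5) == 1.0
        assert km.survival_at(3.0) == 0.0

    def test_hand_product_limit_with_censoring(self):
        # {6+, 7, 9+, 10, 11+}: S(7) = 3/4, S(10) = 3/8
        km = km_estimate([6, 7, 9, 10, 11], [False, True, False, True, False])
        assert km.survival_at(7) == pytest.approx(3 / 4)
        assert km.survival_at(10) == pytest.approx(3 / 8)

    def test_no_events_flat_at_one(self):
        km = km_estimate([2.0, 3.0], [False, False])
        assert km.survival_at(10.0) == 1.0 and km.se_at(10.0) == 0.0

    def test_greenwood_equals_binomial_variance_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 300)
        km = km_estimate(t, np.ones(300, bool))
        s = km.survival
        expected_se = np.sqrt(s * (1 - s) / 300)
        np.testing.assert_allclose(km.se, expected_se, atol=1e-12)

    def test_matches_lifelines_on_censored_data(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(3.0, 200)
        c = rng.uniform(0, 6, 200)
        obs, ev = np.minimum(t, c), t <= c
        km = km_estimate(obs, ev)
        kmf = KaplanMeierFitter().fit(obs, ev)
        ours = km.survival_at(km.times)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_left_truncation_risk_sets(self):
        # subject entering at t=5 is not at risk for the event at t=2
        km_plain = km_estimate([2, 8], [True, True])
        km_trunc = km_estimate([2, 8], [True, True], entry=[0, 5])
        assert km_plain.survival_at(2) == 0.5
        assert km_trunc.survival_at(2) == 0.0  # only one subject at risk

    def test_positive_times_required(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])

    def test_censoring_km_swaps_roles(self):
        km = censoring_km([1, 2, 3], [True, False, True])
        assert km.times.tolist() == [2]


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [True] * 6
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, df, p = logrank_test(t, g, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_single_group_is_usage_error(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], ["a", "a"], [True, True])

    def test_three_groups_df(self):
        chi2, df, p = logrank_test([1, 2, 3, 4, 5, 6], list("aabbcc"), [True] * 6)
        assert df == 2

    def test_equals_cox_score_test_on_untied_data(self):
        """Two-group log-rank chi2 equals the score statistic U^2/I of a
        single binary-covariate Cox model at beta = 0."""
        rng = np.random.default_rng(5)
        t = rng.exponential(1.0, 40)
        g = rng.random(40) < 0.5
        e = rng.random(40) < 0.8
        chi2, _, _ = logrank_test(t, np.where(g, "a", "b"), e)
        rs = mcox._RiskSums(np.zeros(40), t, e)
        _, score, info = mcox._efron_terms(rs, g.astype(float)[:, None], np.zeros(1))
        assert chi2 == pytest.approx(score[0] ** 2 / info[0, 0], abs=1e-8)


class TestCountingProcess:
    def _cohort(self, rt, T, event):
        return pd.DataFrame([{"patient_id": "p1", "pfs_years": T, "pfs_event": event,
                              "os_years": T, "os_event": event,
                              "rt_start_years": rt}])

    def test_rt_before_event_splits(self):
        rows = build_td_dataset(self._cohort(0.25, 2.0, True))
        assert len(rows) == 2
        r0, r1 = rows.iloc[0], rows.iloc[1]
        assert (r0["start"], r0["stop"], r0["rt"], r0["event"]) == (0.0, 0.25, 0, False)
        assert (r1["start"], r1["stop"], r1["rt"], r1["event"]) == (0.25, 2.0, 1, True)

    def test_no_rt_single_row(self):
        rows = build_td_dataset(self._cohort(np.nan, 5.0, False))
        assert len(rows) == 1
        assert (rows.iloc[0]["rt"], rows.iloc[0]["event"]) == (0, False)

    def test_rt_after_exit_never_counted(self):
        rows = build_td_dataset(self._cohort(6.0, 2.0, True))
        assert len(rows) == 1 and rows.iloc[0]["rt"] == 0 and rows.iloc[0]["event"]

    def test_rt_at_zero_is_exposed_from_entry(self):
        rows = build_td_dataset(self._cohort(0.0, 2.0, True))
        assert len(rows) == 1 and rows.iloc[0]["rt"] == 1

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            build_td_dataset(self._cohort(np.nan, -1.0, True))
        with pytest.raises(ValueError):
            build_td_dataset(self._cohort(-0.5, 2.0, True))


def _sim_td_cohort(rng, n, beta_x=np.log(2), beta_rt=-0.5, rt_time=0.25,
                   censor=(0.5, 8.0)):
    """Piecewise-exponential simulation with a known time-dependent RT effect."""
    rows = []
    for i in range(n):
        x = float(rng.random() < 0.5)
        has_rt = rng.random() < 0.7
        lam0 = 0.25 * np.exp(beta_x * x)
        u = rng.exponential(1.0)
        # cumulative hazard: lam0 * t for t < rt_time, then rate lam0*exp(beta_rt)
        if not has_rt or u < lam0 * rt_time:
            T = u / lam0
        else:
            T = rt_time + (u - lam0 * rt_time) / (lam0 * np.exp(beta_rt))
        C = rng.uniform(*censor)
        rows.append({"patient_id": f"p{i}", "pfs_years": min(T, C),
                     "pfs_event": T <= C, "os_years": min(T, C), "os_event": T <= C,
                     "rt_start_years": rt_time if has_rt else np.nan, "x": x})
    return pd.DataFrame(rows)


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
        t = np.array([2.0, 5.0, 1.0, 3.0, 4.0, 6.0])
        e = np.array([1, 1, 1, 0, 1, 1], bool)

        def negpl(b):
            ll = 0.0
            for i in np.flatnonzero(e):
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[t >= t[i]])))
            return -ll

        brute = minimize_scalar(negpl, bounds=(-5, 5), method="bounded",
                                options={"xatol": 1e-12})
        sol = mcox.fit_cox(np.zeros(6), t, e, x[:, None])
        assert sol.beta[0] == pytest.approx(brute.x, abs=1e-6)
        assert sol.loglik == pytest.approx(-brute.fun, abs=1e-9)

    def test_matches_lifelines_time_varying(self):
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(11)
        cohort = _sim_td_cohort(rng, 300)
        rows = build_td_dataset(cohort)
        fit = cox_fit(rows, ["x", "rt"])
        ctv = CoxTimeVaryingFitter()
        ctv.fit(rows[["patient_id", "start", "stop", "event", "x", "rt"]],
                id_col="patient_id", start_col="start", stop_col="stop",
                event_col="event")
        np.testing.assert_allclose(fit.coef, ctv.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, ctv.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.loglik == pytest.approx(ctv.log_likelihood_, abs=1e-6)

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 120
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "T": np.ceil(rng.exponential(3.0, n)),  # heavy ties
            "E": rng.random(n) < 0.7,
            "x": rng.normal(size=n),
        })
        rows = df.rename(columns={"T": "stop", "E": "event"}).assign(start=0.0)
        fit = cox_fit(rows, ["x"])
        cph = CoxPHFitter().fit(df[["T", "E", "x"]], "T", "E")
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)

    def test_split_invariance(self):
        rng = np.random.default_rng(9)
        n = 80
        t = rng.exponential(2, n) + 0.1
        e = rng.random(n) < 0.7
        x = rng.normal(size=n)
        rows = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                             "start": 0.0, "stop": t, "event": e, "x": x})
        fit0 = cox_fit(rows, ["x"])
        # split every subject at an arbitrary time without changing covariates
        parts = []
        for _, r in rows.iterrows():
            cut = r["stop"] / 2
            parts.append({**r, "stop": cut, "event": False})
            parts.append({**r, "start": cut})
        fit1 = cox_fit(pd.DataFrame(parts), ["x"])
        assert fit1.coef[0] == pytest.approx(fit0.coef[0], abs=1e-8)
        assert fit1.loglik == pytest.approx(fit0.loglik, abs=1e-8)

    def test_constant_covariate_is_rank_error(self):
        rows = pd.DataFrame({"patient_id": list("abcd"), "start": 0.0,
                             "stop": [1.0, 2, 3, 4], "event": True, "x": 1.0})
        with pytest.raises(mcox.RankError):
            cox_fit(rows, ["x"])

    def test_no_events_is_error(self):
        rows = pd.DataFrame({"patient_id": list("ab"), "start": 0.0,
                             "stop": [1.0, 2.0], "event": False, "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(rows, ["x"])

    def test_aic_identity_and_summary(self):
        rng = np.random.default_rng(12)
        cohort = _sim_td_cohort(rng, 200)
        fit = cox_fit(build_td_dataset(cohort), ["x", "rt"])
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        s = fit.summary()
        assert list(s.index) == ["x", "rt"]
        assert np.all(s["hr_ci_low"] < s["hr"]) and np.all(s["hr"] < s["hr_ci_high"])
        assert 0 <= fit.global_p <= 1

    def test_adding_informative_covariate_lowers_aic(self):
        rng = np.random.default_rng(21)
        aic_small, aic_big = [], []
        for _ in range(15):
            cohort = _sim_td_cohort(rng, 150, beta_x=1.2)
            rows = build_td_dataset(cohort)
            aic_small.append(cox_fit(rows, ["rt"]).aic)
            aic_big.append(cox_fit(rows, ["rt", "x"]).aic)
        assert np.mean(aic_big) < np.mean(aic_small)


class TestConcordance:
    def test_matches_lifelines_on_time_fixed_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(3)
        n = 150
        t = rng.exponential(2, n)
        e = rng.random(n) < 0.7
        lp = rng.normal(size=n)
        rows = pd.DataFrame({"patient_id": np.arange(n), "start": 0.0,
                             "stop": t, "event": e})
        ours = concordance_on_rows(rows, lp)
        theirs = concordance_index(t, -lp, e)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_horizon_truncation_drops_late_events(self):
        rows = pd.DataFrame({"patient_id": list("abc"), "start": 0.0,
                             "stop": [1.0, 20.0, 10.0], "event": [True, False, True]})
        lp = np.array([1.0, 0.0, 2.0])
        # full: event a vs {b, c} gives 1/2; event c vs {b} gives 1/1 -> 2/3
        assert concordance_on_rows(rows, lp) == pytest.approx(2 / 3)
        # truncated at 5: only event a remains -> 1/2
        assert concordance_on_rows(rows, lp, horizon=5.0) == pytest.approx(1 / 2)


class TestChiSquareAndKappa:
    def test_identical_rows_give_null(self):
        stat, df, p = pearson_chisq([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, df, p = pearson_chisq([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_staging_contingency_is_significant(self):
        # 3x2 staging table (R0/M0, R+/M0, M+) x (discovery, validation)
        stat, df, p = pearson_chisq([[86, 12, 196], [110, 90, 223]])
        assert p < 0.05

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            pearson_chisq([[0, 0], [1, 2]])

    def test_kappa_perfect_agreement(self):
        assert cohens_kappa(np.diag([5, 7, 9])) == 1.0

    def test_kappa_hand_example(self):
        assert cohens_kappa([[40, 10], [10, 40]]) == pytest.approx(0.6)

    def test_kappa_independent_raters_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 100_000)
        b = rng.integers(0, 3, 100_000)
        m = pd.crosstab(a, b).to_numpy()
        assert abs(cohens_kappa(m)) < 0.02

    def test_kappa_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        m = np.array([[30, 5, 2], [4, 40, 6], [1, 7, 25]])
        assert cohens_kappa(m) == pytest.approx(sm_kappa(m, return_results=False))

    def test_kappa_degenerate_marginals(self):
        # all mass on one agreeing cell: chance agreement is 1 but so is
        # observed agreement; defined as perfect
        assert cohens_kappa([[7, 0], [0, 0]]) == 1.0
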