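import warnings

import numpy as np
import pandas as pd
import pytest

from mbrisk.evaluate import (PRESET_SPECS, ModelSpec, bootstrap_cv, brier_curve,
                             build_design, compare_models, external_validate,
                             evaluate_fit, fit_model, incident_dynamic_auc,
                             integrated_brier, predict_survival_matrix)
from mbrisk.survival import build_td_dataset


def _rows(t, e, start=None):
    return pd.DataFrame({"patient_id": [f"p{i}" for i in range(len(t))],
                         "start": 0.0 if start is None else start,
                         "stop": t, "event": e})


class TestIncidentDynamicAUC:
    def test_perfect_predictor_gives_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, 50) + 0.01
        e = np.ones(50, bool)
        curve, iauc = incident_dynamic_auc(_rows(t, e), -t, horizon=np.inf)
        assert (curve["auc"] == 1.0).all() and iauc == 1.0

    def test_uninformative_predictor_near_half(self):
        rng = np.random.default_rng(1)
        n = 2000
        t = rng.exponential(2, n)
        e = rng.random(n) < 0.8
        lp = rng.normal(size=n)
        _, iauc = incident_dynamic_auc(_rows(t, e), lp, horizon=5.0)
        assert iauc == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_pair_counting(self):
        """n=8 hand-built risk sets, including a predictor tie."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1], bool)
        lp = np.array([2.0, 1.0, 1.5, 1.5, 0.5, 1.0, 0.0, -1.0])
        curve, iauc = incident_dynamic_auc(_rows(t, e), lp, horizon=10.0)
        # brute force, straight from the definition
        expected = []
        for ti in t[e]:
            case = lp[(t == ti) & e][0]
            ctrl = lp[(t >= ti) & ~((t == ti) & e)]
            if len(ctrl) == 0:
                continue  # no at-risk survivor to compare against
            auc = np.mean((case > ctrl) + 0.5 * (case == ctrl))
            expected.append(auc)
        np.testing.assert_allclose(curve["auc"].to_numpy(), expected, atol=1e-12)
        assert iauc == pytest.approx(np.mean(expected))

    def test_no_events_before_horizon_errors(self):
        with pytest.raises(ValueError):
            incident_dynamic_auc(_rows([6.0, 7.0], [True, True]),
                                 np.array([0.0, 1.0]), horizon=5.0)


class TestBrier:
    def test_constant_half_prediction_without_censoring(self):
        t = np.linspace(1, 10, 20)
        e = np.ones(20, bool)
        grid = np.array([0.0, 2.0, 5.0, 9.0])
        S = np.full((20, 4), 0.5)
        np.testing.assert_allclose(brier_curve(S, t, e, grid), 0.25, atol=1e-15)

    def test_perfect_predictions_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        grid = np.array([0.5, 1.5, 2.5, 3.5])
        S = (t[:, None] > grid[None, :]).astype(float)
        np.testing.assert_allclose(brier_curve(S, t, e, grid), 0.0, atol=1e-15)

    def test_no_censoring_equals_brute_force_mse(self):
        rng = np.random.default_rng(2)
        n = 60
        t = rng.exponential(3, n)
        e = np.ones(n, bool)
        grid = np.linspace(0.2, 8, 15)
        S = np.clip(rng.random((n, len(grid))), 0, 1)
        got = brier_curve(S, t, e, grid)
        want = [np.mean(((t > g).astype(float) - S[:, j]) ** 2)
                for j, g in enumerate(grid)]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_ipcw_matches_hand_computation(self):
        """Worked n=10 dataset with 20% censoring against a from-scratch
        Graf estimator built on a reverse Kaplan-Meier from lifelines."""
        from lifelines import KaplanMeierFitter

        t = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 1], bool)
        rng = np.random.default_rng(3)
        grid = np.array([1.5, 3.5, 5.5])
        S = np.round(rng.random((10, 3)), 3)
        got = brier_curve(S, t, e, grid)
        G = KaplanMeierFitter().fit(t, ~e)
        for j, g in enumerate(grid):
            total = 0.0
            for i in range(10):
                if t[i] <= g and e[i]:
                    w = 1.0 / float(G.survival_function_at_times(t[i] - 1e-9).iloc[0])
                    total += w * S[i, j] ** 2
                elif t[i] > g:
                    w = 1.0 / float(G.survival_function_at_times(g).iloc[0])
                    total += w * (1 - S[i, j]) ** 2
            assert got[j] == pytest.approx(total / 10, abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import brier_score
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        n = 200
        t = rng.exponential(3, n) + 0.01
        c = rng.uniform(0.5, 9, n)
        obs, ev = np.minimum(t, c), t <= c
        grid = np.quantile(obs[ev], [0.2, 0.4, 0.6])
        S = np.exp(-0.2 * np.outer(rng.uniform(0.5, 2, n), grid))
        y = Surv.from_arrays(ev, obs)
        _, theirs = brier_score(y, y, S, grid)
        ours = brier_curve(S, obs, ev, grid)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_bad_prediction_matrix_shape(self):
        with pytest.raises(ValueError):
            brier_curve(np.zeros((3, 2)), [1, 2], [True, True], [1.0, 2.0])


class TestIntegratedBrier:
    def test_constant_curve(self):
        assert integrated_brier([0.25, 0.25, 0.25], [0.0, 2.0, 5.0], 5.0) == 0.25

    def test_linear_curve_closed_form(self):
        assert integrated_brier([0.0, 0.2], [0.0, 5.0], 5.0) == pytest.approx(0.1)

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            integrated_brier([], [], 5.0)

    def test_horizon_beyond_grid_errors(self):
        with pytest.raises(ValueError):
            integrated_brier([0.1, 0.2], [0.0, 3.0], 5.0)


class TestModelFitting:
    def test_design_blocks(self, simple_cohort):
        rows = build_td_dataset(simple_cohort)
        X, levels = build_design(rows, ("staging", "rt", "myc", "mycn", "wca", "cm"))
        assert set(X.columns) >= {"m_plus", "rt", "myc_amp", "mycn_amp", "wca_fr"}
        assert set(levels["cm"]) == {"SR", "HR", "VHR"}  # LR is the reference

    def test_unseen_level_in_validation_errors(self, simple_cohort):
        rows = build_td_dataset(simple_cohort)
        _, levels = build_design(rows, ("cm",), )
        bad = rows.copy()
        bad.loc[bad.index[0], "cm"] = "XX"
        with pytest.raises(ValueError, match="unseen"):
            build_design(bad, ("cm",), levels)

    def test_predicted_survival_matches_closed_form_without_rt(self, simple_cohort):
        spec = ModelSpec("no_rt", ("staging",))
        model = fit_model(spec, simple_cohort)
        grid = np.array([0.5, 1.0, 3.0, 5.0])
        S = predict_survival_matrix(model, simple_cohort, grid)
        X, _ = build_design(simple_cohort.assign(rt=0.0), spec.blocks, model.levels)
        lp = model.fit.linear_predictor(X[model.fit.covariates])
        H = model.fit.cumhaz_at(grid)
        np.testing.assert_allclose(S, np.exp(-np.exp(lp)[:, None] * H[None, :]),
                                   atol=1e-12)
        assert np.all(np.diff(S, axis=1) <= 1e-12)  # monotone non-increasing

    def test_rt_path_prediction_interpolates_exposure(self, simple_cohort):
        model = fit_model(PRESET_SPECS["clinical"], simple_cohort)
        grid = np.array([0.1, 1.0, 4.0])
        S = predict_survival_matrix(model, simple_cohort, grid)
        assert S.shape == (len(simple_cohort), 3)
        assert np.all((S >= 0) & (S <= 1))

    def test_evaluate_fit_reports_all_metrics(self, simple_cohort):
        metrics = evaluate_fit(fit_model(PRESET_SPECS["clinical"], simple_cohort),
                               simple_cohort, horizon=5.0)
        for key in ("ibs", "c_index", "c_index_full", "integrated_auc", "aic"):
            assert np.isfinite(metrics[key])


class TestBootstrapCV:
    def test_deterministic_given_seed(self, simple_cohort):
        a = bootstrap_cv(PRESET_SPECS["clinical"], simple_cohort, B=5, seed=42)
        b = bootstrap_cv(PRESET_SPECS["clinical"], simple_cohort, B=5, seed=42)
        np.testing.assert_array_equal(a.ibs_replicates, b.ibs_replicates)
        np.testing.assert_array_equal(a.c_replicates, b.c_replicates)

    def test_single_subject_cohort_errors(self, simple_cohort):
        with pytest.raises(ValueError):
            bootstrap_cv(PRESET_SPECS["clinical"], simple_cohort.iloc[:1], B=5)

    def test_b_below_two_errors(self, simple_cohort):
        with pytest.raises(ValueError):
            bootstrap_cv(PRESET_SPECS["clinical"], simple_cohort, B=1)

    def test_prognostic_model_beats_noise_model(self):
        """A covariate with true HR 4 should cross-validate better than a
        pure-noise covariate on the same outcomes."""
        rng = np.random.default_rng(7)
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) / np.exp(np.log(4) * x)
        c = rng.uniform(0.5, 6, n)
        cohort = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "pfs_years": np.minimum(t, c), "pfs_event": t <= c,
            "os_years": np.minimum(t, c), "os_event": t <= c,
            "rt_start_years": np.nan,
            "m_stage": np.where(x > 0, "M+", "M0"),       # prognostic block
            "myc_amp": rng.random(n) < 0.5,               # noise block
        })
        prog = bootstrap_cv(ModelSpec("prog", ("staging",)), cohort, B=20,
                            horizon=5.0, seed=1)
        noise = bootstrap_cv(ModelSpec("noise", ("myc",)), cohort, B=20,
                             horizon=5.0, seed=1)
        assert prog.c_index > noise.c_index
        assert prog.ibs < noise.ibs


class TestExternalValidation:
    def test_identical_cohort_reproduces_apparent_metrics(self, simple_cohort):
        model = fit_model(PRESET_SPECS["clinical"], simple_cohort)
        apparent = evaluate_fit(model, simple_cohort, horizon=5.0)
        external = external_validate(model, simple_cohort, horizon=5.0)
        assert external["ibs"] == pytest.approx(apparent["ibs"], abs=1e-12)
        assert external["c_index"] == pytest.approx(apparent["c_index"], abs=1e-12)

    def test_unseen_subgroup_level_errors(self, simple_cohort):
        model = fit_model(ModelSpec("sub", ("subgroup",)), simple_cohort)
        val = simple_cohort.copy()
        val["subgroup"] = "I"  # absent from discovery
        with pytest.raises(ValueError, match="unseen"):
            external_validate(model, val, horizon=5.0)

    def test_exchangeable_cohorts_agree(self):
        from mbrisk.pipeline import analysis_frame, stratify_cohort
        from mbrisk.simulate import (CohortConfig, cohort_to_frame,
                                     generate_cohort, labels_to_frame)

        frames = []
        for seed in (100, 200):
            cfg = CohortConfig(n_patients=2000, seed=seed)
            pats, labs, truths = generate_cohort(cfg)
            cohort = cohort_to_frame(pats)
            labels = labels_to_frame(pats, labs)
            calls = pd.DataFrame([{
                "sample_id": t.patient_id,
                "chr7_gain": ("7p", "gain") in t.arm_aberrations,
                "chr8_loss": ("8p", "loss") in t.arm_aberrations,
                "chr11_loss": ("11p", "loss") in t.arm_aberrations,
                "i17q": ("17p", "loss") in t.arm_aberrations,
                "myc_amp": t.myc_amp, "mycn_amp": t.mycn_amp,
                "wca_phenotype": "FR" if sum((
                    ("7p", "gain") in t.arm_aberrations,
                    ("8p", "loss") in t.arm_aberrations,
                    ("11p", "loss") in t.arm_aberrations)) >= 2 else "SR",
            } for t in truths])
            strata = stratify_cohort(cohort, labels, calls)
            frames.append(analysis_frame(cohort, labels, calls, strata))
        disc, val = frames
        model = fit_model(PRESET_SPECS["cm"], disc)
        apparent = evaluate_fit(model, disc, horizon=5.0)
        external = external_validate(model, val, horizon=5.0)
        assert external["c_index"] == pytest.approx(apparent["c_index"], abs=0.05)


class TestCompareModels:
    def test_identical_specs_identical_metrics(self, simple_cohort):
        specs = [ModelSpec("a", ("staging", "myc")), ModelSpec("b", ("staging", "myc"))]
        comp = compare_models(specs, simple_cohort, horizon=5.0)
        a = comp.metrics.loc["a"].drop("n_covariates")
        b = comp.metrics.loc["b"].drop("n_covariates")
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_single_spec_is_usage_error(self, simple_cohort):
        with pytest.raises(ValueError):
            compare_models([PRESET_SPECS["clinical"]], simple_cohort, horizon=5.0)

    def test_failing_spec_is_flagged_not_fatal(self, simple_cohort):
        cohort = simple_cohort.copy()
        cohort["myc_amp"] = True  # constant covariate -> rank error
        comp = compare_models([ModelSpec("ok", ("staging",)),
                               ModelSpec("bad", ("myc",))], cohort, horizon=5.0)
        assert comp.failed == ["bad"]
        assert comp.best_model == "ok"
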