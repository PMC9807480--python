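"""Prognostic-model comparison: incident/dynamic ROC AUC, IPCW prediction
error (Brier) curves, integrated Brier score, concordance, bootstrap
cross-validation, and frozen-model external validation.

Every model shares the clinical backbone (staging, time-dependent CSI, MYC
and MYCN amplification) and differs in the biological block added on top
(molecular group, subgroup, WCA phenotype, combinations, or the integrated
clinico-molecular stratum). Models are ranked by the AUC of an incident/
dynamic ROC analysis of 5-year PFS; prediction accuracy is compared by the
integrated Brier score (IBS) and the concordance index, cross-validated by
bootstrap resampling with out-of-bag evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cox import RankError, ConvergenceError
from .survival import (CoxFit, build_td_dataset, censoring_km, concordance_on_rows,
                       cox_fit)

__all__ = [
    "ModelSpec", "FittedModel", "ModelComparison", "BootstrapCV",
    "PRESET_SPECS", "build_design", "fit_model", "predict_survival_matrix",
    "incident_dynamic_auc", "brier_curve", "integrated_brier",
    "evaluate_fit", "bootstrap_cv", "external_validate", "compare_models",
]

BACKBONE = ("staging", "rt", "myc", "mycn")

_SUBGROUP_REF = "VIII"   # most frequent subgroup
_CM_REF = "LR"


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate recipe, as blocks resolved against the cohort table."""

    name: str
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        known = {"staging", "rt", "myc", "mycn", "group", "subgroup", "wca", "cm"}
        unknown = set(self.blocks) - known
        if unknown:
            raise ValueError(f"unknown design blocks {sorted(unknown)}")


PRESET_SPECS: dict[str, ModelSpec] = {
    "clinical": ModelSpec("clinical", BACKBONE),
    "group": ModelSpec("group", BACKBONE + ("group",)),
    "subgroup": ModelSpec("subgroup", BACKBONE + ("subgroup",)),
    "wca": ModelSpec("wca", BACKBONE + ("wca",)),
    "wca_group": ModelSpec("wca_group", BACKBONE + ("wca", "group")),
    "wca_subgroup": ModelSpec("wca_subgroup", BACKBONE + ("wca", "subgroup")),
    "cm": ModelSpec("cm", BACKBONE + ("cm",)),
}


def _dummies(series: pd.Series, ref: str, levels: Sequence[str] | None,
             prefix: str) -> tuple[pd.DataFrame, list[str]]:
    observed = [str(v) for v in pd.unique(series.dropna())]
    if levels is None:
        levels = sorted(v for v in observed if v != ref)
    else:
        unseen = sorted(set(observed) - set(levels) - {ref})
        if unseen:
            raise ValueError(f"{prefix}: unseen levels {unseen}; "
                             f"model knows {sorted(levels)} (reference {ref!r})")
    out = pd.DataFrame(index=series.index)
    for lv in levels:
        out[f"{prefix}_{lv}"] = (series == lv).astype(float)
    return out, list(levels)


def build_design(frame: pd.DataFrame, blocks: Sequence[str],
                 levels: Mapping[str, list[str]] | None = None
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix columns for the given blocks.

    ``levels`` freezes categorical encodings from a previous fit; unseen
    levels in new data raise, listing the known ones.
    """
    levels = dict(levels or {})
    X = pd.DataFrame(index=frame.index)
    out_levels: dict[str, list[str]] = {}
    for b in blocks:
        if b == "staging":
            X["m_plus"] = (frame["m_stage"] == "M+").astype(float)
        elif b == "rt":
            X["rt"] = frame["rt"].astype(float)
        elif b == "myc":
            X["myc_amp"] = frame["myc_amp"].astype(bool).astype(float)
        elif b == "mycn":
            X["mycn_amp"] = frame["mycn_amp"].astype(bool).astype(float)
        elif b == "group":
            X["group3"] = (frame["group"] == "Group3").astype(float)
        elif b == "wca":
            X["wca_fr"] = (frame["wca_phenotype"] == "FR").astype(float)
        elif b == "subgroup":
            d, lv = _dummies(frame["subgroup"], _SUBGROUP_REF, levels.get("subgroup"),
                             "subgroup")
            X = pd.concat([X, d], axis=1)
            out_levels["subgroup"] = lv
        elif b == "cm":
            d, lv = _dummies(frame["cm"], _CM_REF, levels.get("cm"), "cm")
            X = pd.concat([X, d], axis=1)
            out_levels["cm"] = lv
    return X, out_levels


@dataclass
class FittedModel:
    spec: ModelSpec
    fit: CoxFit
    levels: dict[str, list[str]]
    endpoint: str
    rt_epsilon: float = 0.0

    def linear_predictors(self, rows: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(rows, self.spec.blocks, self.levels)
        return self.fit.linear_predictor(X[self.fit.covariates])


def fit_model(spec: ModelSpec, cohort: pd.DataFrame,
              endpoint: Literal["PFS", "OS"] = "PFS",
              rt_epsilon: float = 0.0,
              beta0: np.ndarray | None = None) -> FittedModel:
    """Build the counting-process dataset for ``endpoint`` and fit ``spec``."""
    rows = build_td_dataset(cohort, endpoint, rt_epsilon)
    X, levels = build_design(rows, spec.blocks)
    rows = pd.concat([rows[["patient_id", "start", "stop", "event"]], X], axis=1)
    fit = cox_fit(rows, list(X.columns), beta0=beta0)
    return FittedModel(spec, fit, levels, endpoint, rt_epsilon)


def predict_survival_matrix(model: FittedModel, cohort: pd.DataFrame,
                            grid: np.ndarray) -> np.ndarray:
    """Predicted survival S_i(t) for each patient at each grid time.

    The covariate path is known in advance (RT starts at ``rt_start_years``),
    so the survival function integrates the baseline hazard piecewise over
    the pre-RT and post-RT segments with the Breslow-type baseline carried
    by the fit.
    """
    grid = np.asarray(grid, float)
    frame0 = cohort.copy()
    frame0["rt"] = 0.0
    X0, _ = build_design(frame0, model.spec.blocks, model.levels)
    lp0 = model.fit.linear_predictor(X0[model.fit.covariates])
    H = model.fit.cumhaz_at(grid)  # (g,)
    if "rt" not in model.fit.covariates:
        return np.exp(-np.exp(lp0)[:, None] * H[None, :])
    frame1 = cohort.copy()
    frame1["rt"] = 1.0
    X1, _ = build_design(frame1, model.spec.blocks, model.levels)
    lp1 = model.fit.linear_predictor(X1[model.fit.covariates])
    t0 = cohort["rt_start_years"].to_numpy(float) if "rt_start_years" in cohort else \
        np.full(len(cohort), np.inf)
    t0 = np.where(np.isnan(t0), np.inf, t0)
    t0 = np.where(t0 <= model.rt_epsilon, 0.0, t0)
    H0_t0 = np.where(np.isfinite(t0), model.fit.cumhaz_at(np.where(np.isfinite(t0), t0, 0.0)),
                     np.inf)
    pre = np.minimum(H[None, :], H0_t0[:, None])
    post = np.clip(H[None, :] - H0_t0[:, None], 0.0, None)
    cum = np.exp(lp0)[:, None] * pre + np.exp(lp1)[:, None] * post
    return np.exp(-cum)


# ---------------------------------------------------------------------------
# incident/dynamic ROC


def incident_dynamic_auc(rows: pd.DataFrame, lp: np.ndarray, horizon: float
                         ) -> tuple[pd.DataFrame, float]:
    """Incident/dynamic time-dependent ROC AUC on counting-process rows.

    At each event time t <= horizon, AUC(t) is the probability that the
    predictor of a subject failing at t exceeds that of a randomly chosen
    subject still at risk (ties count one half). The integrated AUC is the
    event-count-weighted average over event times up to the horizon.
    """
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    event = rows["event"].to_numpy(bool)
    lp = np.asarray(lp, float)
    times = np.unique(stop[event & (stop <= horizon)])
    if len(times) == 0:
        raise ValueError("no events before the horizon")
    recs = []
    for t in times:
        case = event & (stop == t)
        at_risk = (start < t) & (stop >= t)
        ctrl = at_risk & ~case
        if not ctrl.any():
            continue
        cases_lp, ctrl_lp = lp[case], lp[ctrl]
        gt = (cases_lp[:, None] > ctrl_lp[None, :]).sum()
        eq = (cases_lp[:, None] == ctrl_lp[None, :]).sum()
        auc = (gt + 0.5 * eq) / (case.sum() * ctrl.sum())
        recs.append((float(t), float(auc), int(case.sum()), int(ctrl.sum())))
    curve = pd.DataFrame(recs, columns=["time", "auc", "n_events", "n_controls"])
    weights = curve["n_events"].to_numpy(float)
    integrated = float(np.average(curve["auc"].to_numpy(), weights=weights))
    return curve, integrated


# ---------------------------------------------------------------------------
# IPCW Brier / prediction error


def brier_curve(surv_pred: np.ndarray, durations: Sequence[float],
                events: Sequence[bool], grid: Sequence[float]) -> np.ndarray:
    """Graf's IPCW Brier score at each grid time.

    ``surv_pred[i, j]`` is subject i's predicted survival at ``grid[j]``.
    Subjects with an observed event before t contribute S(t)^2 weighted by
    1/G(T-); subjects still event-free at t contribute (1-S(t))^2 weighted
    by 1/G(t); subjects censored before t contribute nothing (their mass is
    carried by the weights). G is the KM estimate of the censoring
    distribution.
    """
    T = np.asarray(durations, float)
    E = np.asarray(events, bool)
    grid = np.asarray(grid, float)
    S = np.asarray(surv_pred, float)
    if S.shape != (len(T), len(grid)):
        raise ValueError(f"prediction matrix must be (n_subjects={len(T)}, "
                         f"n_times={len(grid)}), got {S.shape}")
    if np.any(S < -1e-9) or np.any(S > 1 + 1e-9):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    G = censoring_km(T, E)
    G_at_T = np.asarray(G.survival_before(T), float)       # G(T-)
    G_at_grid = np.asarray(G.survival_at(grid), float)     # G(t)
    n = len(T)
    past_event = E[:, None] & (T[:, None] <= grid[None, :])   # (n, g)
    future = T[:, None] > grid[None, :]
    if np.any(past_event & (G_at_T == 0)[:, None]):
        j = int(np.argmax(np.any(past_event & (G_at_T == 0)[:, None], axis=0)))
        raise ValueError(f"censoring survival is zero before time {grid[j]}; "
                         "IPCW weights undefined")
    bad = future.any(axis=0) & (G_at_grid == 0)
    if bad.any():
        raise ValueError(f"censoring survival is zero at time "
                         f"{grid[int(np.argmax(bad))]}; IPCW weights undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        w_event = np.where(G_at_T > 0, 1.0 / G_at_T, 0.0)[:, None]
        w_future = np.where(G_at_grid > 0, 1.0 / G_at_grid, 0.0)[None, :]
    contrib = past_event * S**2 * w_event + future * (1 - S) ** 2 * w_future
    return contrib.sum(axis=0) / n


def integrated_brier(curve: Sequence[float], times: Sequence[float],
                     horizon: float) -> float:
    """Trapezoid time-average of the prediction error curve over [0, horizon]."""
    c = np.asarray(curve, float)
    t = np.asarray(times, float)
    if len(c) == 0 or len(c) != len(t):
        raise ValueError("empty or mismatched prediction error curve")
    if horizon > t[-1] + 1e-12:
        raise ValueError(f"horizon {horizon} beyond last grid point {t[-1]}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    keep = t <= horizon + 1e-12
    return float(np.trapezoid(c[keep], t[keep]) / (t[keep][-1] - t[keep][0]))


def _eval_grid(durations: np.ndarray, events: np.ndarray, horizon: float) -> np.ndarray:
    """Evaluation grid: 0, every event time up to the horizon, the horizon."""
    ev = np.unique(durations[events & (durations <= horizon)])
    return np.unique(np.concatenate([[0.0], ev, [horizon]]))


def evaluate_fit(model: FittedModel, cohort: pd.DataFrame, horizon: float
                 ) -> dict[str, float]:
    """Apparent IBS, concordance (horizon-truncated and full) and AUC."""
    tcol, ecol = (("pfs_years", "pfs_event") if model.endpoint == "PFS"
                  else ("os_years", "os_event"))
    T = cohort[tcol].to_numpy(float)
    E = cohort[ecol].to_numpy(bool)
    grid = _eval_grid(T, E, horizon)
    S = predict_survival_matrix(model, cohort, grid)
    bs = brier_curve(S, T, E, grid)
    rows = build_td_dataset(cohort, model.endpoint, model.rt_epsilon)
    lp = model.linear_predictors(rows)
    auc_curve, iauc = incident_dynamic_auc(rows, lp, horizon)
    return {
        "ibs": integrated_brier(bs, grid, horizon),
        "c_index": concordance_on_rows(rows, lp, horizon=horizon),
        "c_index_full": concordance_on_rows(rows, lp),
        "integrated_auc": iauc,
        "auc_last_event": float(auc_curve["auc"].iloc[-1]),
        "aic": model.fit.aic,
    }


# ---------------------------------------------------------------------------
# bootstrap cross-validation and external validation


@dataclass
class BootstrapCV:
    spec_name: str
    ibs: float
    c_index: float
    ibs_replicates: np.ndarray
    c_replicates: np.ndarray
    n_skipped: int
    seed: int


def bootstrap_cv(spec: ModelSpec, cohort: pd.DataFrame, B: int = 500,
                 horizon: float = 5.0, seed: int = 0,
                 endpoint: Literal["PFS", "OS"] = "PFS",
                 rt_epsilon: float = 0.0) -> BootstrapCV:
    """Out-of-bag bootstrap cross-validation of IBS and concordance.

    Each replicate refits the model (including the counting-process split)
    on a resample of patients and evaluates on the out-of-bag patients.
    Replicates whose resample has no events or whose fit degenerates are
    skipped and counted.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    if len(cohort) < 2:
        raise ValueError("cohort too small for bootstrap cross-validation")
    tcol, ecol = (("pfs_years", "pfs_event") if endpoint == "PFS"
                  else ("os_years", "os_event"))
    if not cohort[ecol].any():
        raise ValueError("no events in cohort")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    cohort = cohort.reset_index(drop=True)
    # apparent fit warm-starts every bootstrap refit
    try:
        beta0 = fit_model(spec, cohort, endpoint, rt_epsilon).fit.coef
    except (RankError, ConvergenceError):
        beta0 = None
    ibs_vals, c_vals = [], []
    skipped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        train = cohort.iloc[idx].copy()
        train["patient_id"] = [f"b{b}_{i}" for i in range(n)]
        test = cohort.iloc[oob]
        if not train[ecol].any() or len(test) == 0 or not test[ecol].any():
            skipped += 1
            continue
        try:
            model = fit_model(spec, train, endpoint, rt_epsilon, beta0=beta0)
            T = test[tcol].to_numpy(float)
            E = test[ecol].to_numpy(bool)
            grid = _eval_grid(T, E, horizon)
            S = predict_survival_matrix(model, test, grid)
            bs = brier_curve(S, T, E, grid)
            ibs_vals.append(integrated_brier(bs, grid, horizon))
            rows = build_td_dataset(test, endpoint, rt_epsilon)
            lp = model.linear_predictors(rows)
            c_vals.append(concordance_on_rows(rows, lp, horizon=horizon))
        except (RankError, ConvergenceError, ValueError):
            skipped += 1
    if skipped > 0.05 * B:
        warnings.warn(f"{skipped}/{B} bootstrap replicates skipped", stacklevel=2)
    if not ibs_vals:
        raise RuntimeError("all bootstrap replicates failed")
    return BootstrapCV(spec.name, float(np.mean(ibs_vals)), float(np.mean(c_vals)),
                       np.asarray(ibs_vals), np.asarray(c_vals), skipped, seed)


def external_validate(model: FittedModel, validation: pd.DataFrame, horizon: float
                      ) -> dict[str, float]:
    """Frozen-model validation: predictions from the discovery fit are
    evaluated on the validation cohort only (no refit)."""
    tcol, ecol = (("pfs_years", "pfs_event") if model.endpoint == "PFS"
                  else ("os_years", "os_event"))
    T = validation[tcol].to_numpy(float)
    E = validation[ecol].to_numpy(bool)
    grid = _eval_grid(T, E, horizon)
    S = predict_survival_matrix(model, validation, grid)
    bs = brier_curve(S, T, E, grid)
    rows = build_td_dataset(validation, model.endpoint, model.rt_epsilon)
    lp = model.linear_predictors(rows)
    return {
        "ibs": integrated_brier(bs, grid, horizon),
        "c_index": concordance_on_rows(rows, lp, horizon=horizon),
    }


@dataclass
class ModelComparison:
    metrics: pd.DataFrame                 # one row per model
    auc_curves: dict[str, pd.DataFrame]
    brier_curves: dict[str, pd.DataFrame]
    cv: dict[str, BootstrapCV]
    best_model: str
    failed: list[str]
    seed: int | None = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ModelComparison best={self.best_model!r}\n{self.metrics}>"


def compare_models(specs: Sequence[ModelSpec], cohort: pd.DataFrame,
                   horizon: float = 5.0, B: int = 0, seed: int = 0,
                   endpoint: Literal["PFS", "OS"] = "PFS") -> ModelComparison:
    """Fit all specs on the same counting-process data and rank by the
    integrated incident/dynamic AUC (the model-selection rule); optionally
    bootstrap cross-validate each model's IBS and concordance."""
    if len(specs) < 2:
        raise ValueError("model comparison needs at least two specifications")
    tcol, ecol = (("pfs_years", "pfs_event") if endpoint == "PFS"
                  else ("os_years", "os_event"))
    T = cohort[tcol].to_numpy(float)
    E = cohort[ecol].to_numpy(bool)
    grid = _eval_grid(T, E, horizon)
    rows_list, auc_curves, brier_curves, cv = [], {}, {}, {}
    failed: list[str] = []
    for spec in specs:
        try:
            model = fit_model(spec, cohort, endpoint)
            metrics = evaluate_fit(model, cohort, horizon)
            S = predict_survival_matrix(model, cohort, grid)
            bs = brier_curve(S, T, E, grid)
            rows = build_td_dataset(cohort, endpoint)
            lp = model.linear_predictors(rows)
            auc_curves[spec.name], _ = incident_dynamic_auc(rows, lp, horizon)
            brier_curves[spec.name] = pd.DataFrame({"time": grid, "brier": bs})
            rec = {"model": spec.name, "n_covariates": len(model.fit.covariates),
                   "n_events": model.fit.n_events, **metrics}
            if B >= 2:
                res = bootstrap_cv(spec, cohort, B, horizon, seed, endpoint)
                cv[spec.name] = res
                rec["cv_ibs"] = res.ibs
                rec["cv_c_index"] = res.c_index
            rows_list.append(rec)
        except (RankError, ConvergenceError, ValueError) as err:
            failed.append(spec.name)
            rows_list.append({"model": spec.name, "error": str(err)})
    metrics_df = pd.DataFrame(rows_list).set_index("model")
    ok = metrics_df[~metrics_df.get("integrated_auc", pd.Series(dtype=float)).isna()] \
        if "integrated_auc" in metrics_df else metrics_df.iloc[0:0]
    if ok.empty:
        raise RuntimeError("every model failed to fit")
    best = str(ok["integrated_auc"].idxmax())
    return ModelComparison(metrics_df, auc_curves, brier_curves, cv, best, failed, seed)
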