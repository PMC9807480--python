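"""Survival estimation and tests: Kaplan-Meier with Greenwood standard
errors, log-rank comparisons, Cox regression with a time-dependent
radiotherapy covariate, Pearson chi-square and Cohen's kappa.

Times are years since first tumor surgery throughout. Progression-free
survival (PFS) counts progression, relapse or death from any cause as an
event; overall survival (OS) counts death from any cause; both are censored
at last follow-up. Craniospinal irradiation (CSI) enters the Cox models as
a time-dependent 0/1 covariate via counting-process rows, because its use
is protocol- and age-dependent and only meaningful after it has started.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cox as _cox

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "km_estimate",
    "censoring_km",
    "logrank_test",
    "build_td_dataset",
    "cox_fit",
    "concordance_on_rows",
    "pearson_chisq",
    "cohens_kappa",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood standard errors.

    ``times`` are the distinct event times; the estimate is a right-continuous
    step function equal to 1 before the first event.
    """

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t), right-continuous step lookup."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) else out

    def survival_before(self, t: float | np.ndarray) -> np.ndarray | float:
        """Left limit S(t-): the estimate just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="left")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) else out

    def se_at(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        s = np.concatenate([[0.0], self.se])
        out = s[idx]
        return float(out) if np.isscalar(t) else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.n_events, "survival": self.survival,
                             "se": self.se})


def km_estimate(durations: Sequence[float], events: Sequence[bool],
                entry: Sequence[float] | None = None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Supports delayed entry (left truncation) through ``entry``; the at-risk
    set at time t is ``{i : entry_i < t <= exit_i}``.
    """
    t = np.asarray(durations, float)
    e = np.asarray(events, bool)
    if len(t) == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("all exit times must be positive")
    ent = np.zeros_like(t) if entry is None else np.asarray(entry, float)
    times = np.unique(t[e])
    if len(times) == 0:
        return SurvivalCurve(np.array([]), np.array([]), np.array([]),
                             np.array([], int), np.array([], int), len(t))
    # at risk at tj: entry < tj <= exit, i.e. #{exit >= tj} - #{entry >= tj}
    exits_sorted = np.sort(t)
    entries_sorted = np.sort(ent)
    n_at_risk = ((len(t) - np.searchsorted(exits_sorted, times, side="left"))
                 - (len(t) - np.searchsorted(entries_sorted, times, side="left")))
    ev_sorted = np.sort(t[e])
    d = (np.searchsorted(ev_sorted, times, side="right")
         - np.searchsorted(ev_sorted, times, side="left"))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
        green = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0))
        se = np.where(surv > 0, surv * np.sqrt(green), 0.0)
    return SurvivalCurve(times, surv, se, n_at_risk.astype(int), d.astype(int), len(t))


def censoring_km(durations: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """KM estimate of the censoring distribution G (event roles swapped).

    Used for the inverse-probability-of-censoring weights of the Brier
    score; evaluate with ``survival_before`` for weights at event times.
    """
    e = np.asarray(events, bool)
    return km_estimate(durations, ~e)


def logrank_test(durations: Sequence[float], groups: Sequence, events: Sequence[bool]
                 ) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi2, df, p)."""
    from lifelines.statistics import multivariate_logrank_test

    g = pd.Series(groups)
    labels = g.unique()
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    counts = g.value_counts()
    if (counts == 0).any():
        raise ValueError("empty group in log-rank test")
    res = multivariate_logrank_test(np.asarray(durations, float), g.to_numpy(),
                                    np.asarray(events, bool))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def build_td_dataset(cohort: pd.DataFrame, endpoint: Literal["PFS", "OS"] = "PFS",
                     rt_epsilon: float = 0.0) -> pd.DataFrame:
    """Counting-process rows with the time-dependent RT covariate.

    A patient starting CSI at ``t0`` before exit ``T`` contributes rows
    ``(0, t0, rt=0, no event)`` and ``(t0, T, rt=1, event flag)``; RT after
    exit (or never) gives a single ``rt=0`` row. ``rt_start_years <=
    rt_epsilon`` collapses to a single ``rt=1`` row from entry. All other
    cohort columns are carried along unchanged.
    """
    tcol, ecol = ("pfs_years", "pfs_event") if endpoint == "PFS" else ("os_years", "os_event")
    for c in (tcol, ecol, "patient_id"):
        if c not in cohort.columns:
            raise ValueError(f"cohort table lacks column {c!r}")
    T = cohort[tcol].to_numpy(float)
    ev = cohort[ecol].to_numpy(bool)
    if np.any(T <= 0):
        raise ValueError("non-positive follow-up times")
    n = len(cohort)
    if "rt_start_years" in cohort.columns:
        rt0 = cohort["rt_start_years"].to_numpy(float)
    else:
        rt0 = np.full(n, np.nan)
    if np.any(rt0 < 0):
        bad = cohort.loc[rt0 < 0, "patient_id"].iloc[0]
        raise ValueError(f"{bad}: negative rt_start_years")
    rt0 = np.where(np.isnan(rt0), np.inf, rt0)
    split = (rt0 > rt_epsilon) & (rt0 < T)
    rep = np.repeat(np.arange(n), 1 + split)
    second = np.zeros(len(rep), bool)
    second[np.cumsum(1 + split)[split] - 1] = True  # second row of each split patient
    first_of_split = split[rep] & ~second
    out = cohort.drop(columns=[tcol, ecol]).iloc[rep].reset_index(drop=True)
    out["start"] = np.where(second, rt0[rep], 0.0)
    out["stop"] = np.where(first_of_split, rt0[rep], T[rep])
    out["event"] = ev[rep] & ~first_of_split
    out["rt"] = (second | ((rt0[rep] <= rt_epsilon) & (rt0[rep] < T[rep]))).astype(int)
    return out


@dataclass
class CoxFit:
    """Fitted Cox model on counting-process rows."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_subjects: int
    concordance: float
    converged: bool
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def hr_ci(self) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(0.975)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    @property
    def aic(self) -> float:
        return 2 * len(self.coef) - 2 * self.loglik

    @property
    def global_p(self) -> float:
        """Likelihood-ratio test of the global null (all coefficients zero)."""
        chi2 = 2 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(max(chi2, 0.0), len(self.coef)))

    def linear_predictor(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.covariates].to_numpy(float)
        return np.asarray(X, float) @ self.coef

    def cumhaz_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Baseline cumulative hazard, right-continuous step lookup."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float), side="right")
        h = np.concatenate([[0.0], self.baseline_cumhaz])
        out = h[idx]
        return float(out) if np.isscalar(t) else out

    def summary(self) -> pd.DataFrame:
        lo, hi = self.hr_ci
        z = self.coef / self.se
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hazard_ratios,
            "hr_ci_low": lo, "hr_ci_high": hi,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.covariates)


class _Fenwick:
    """Binary indexed tree over predictor ranks (counts, with removal)."""

    __slots__ = ("t", "n")

    def __init__(self, n: int):
        self.t = np.zeros(n + 1, dtype=np.int64)
        self.n = n

    def add(self, i: int, v: int) -> None:
        while i <= self.n:
            self.t[i] += v
            i += i & -i

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.t[i]
            i -= i & -i
        return int(s)


def concordance_on_rows(rows: pd.DataFrame, lp: np.ndarray,
                        horizon: float | None = None) -> float:
    """Harrell concordance generalised to counting-process rows.

    Each event at time t (optionally restricted to t <= horizon) is compared
    against every other subject at risk at t; ties in the predictor count
    one half. Equals the classic Harrell C on time-fixed data. Implemented
    as a single sweep over decreasing time with a Fenwick tree over
    predictor ranks, O(n log n).
    """
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    event = rows["event"].to_numpy(bool)
    lp = np.asarray(lp, float)
    uniq, rank = np.unique(lp, return_inverse=True)
    rank = rank + 1  # Fenwick is 1-based
    ev_mask = event if horizon is None else event & (stop <= horizon)
    ev_times = np.unique(stop[ev_mask])[::-1]
    # event rows grouped by time (descending)
    ev_rows = np.flatnonzero(ev_mask)
    ev_rows = ev_rows[np.argsort(-stop[ev_rows], kind="stable")]
    ev_bounds = np.searchsorted(-stop[ev_rows], -ev_times, side="left")
    ev_bounds = np.append(ev_bounds, len(ev_rows))
    o_stop = np.argsort(-stop, kind="stable")   # rows entering as t decreases
    o_start = np.argsort(-start, kind="stable")  # rows leaving as t decreases
    bit = _Fenwick(len(uniq))
    active = 0
    pi = pj = 0
    num = den = 0.0
    for k, t in enumerate(ev_times):
        while pi < len(o_stop) and stop[o_stop[pi]] >= t:
            bit.add(int(rank[o_stop[pi]]), 1)
            active += 1
            pi += 1
        while pj < len(o_start) and start[o_start[pj]] >= t:
            bit.add(int(rank[o_start[pj]]), -1)
            active -= 1
            pj += 1
        for i in ev_rows[ev_bounds[k]:ev_bounds[k + 1]]:
            if active <= 1:
                continue
            r = int(rank[i])
            less = bit.prefix(r - 1)
            eq = bit.prefix(r) - less - 1  # exclude the failing row itself
            num += less + 0.5 * eq
            den += active - 1
    if den == 0:
        raise ValueError("no comparable pairs for concordance")
    return num / den


def cox_fit(rows: pd.DataFrame, covariates: Sequence[str],
            beta0: np.ndarray | None = None) -> CoxFit:
    """Fit the Cox model (Efron ties) on counting-process rows.

    ``rows`` needs columns start/stop/event/patient_id plus the covariates.
    ``beta0`` warm-starts the Newton iteration (useful for bootstrap refits).
    """
    covariates = list(covariates)
    X = rows[covariates].to_numpy(float)
    sol = _cox.fit_cox(rows["start"].to_numpy(float), rows["stop"].to_numpy(float),
                       rows["event"].to_numpy(bool), X, beta0=beta0)
    lp = X @ sol.beta
    conc = concordance_on_rows(rows, lp)
    return CoxFit(covariates, sol.beta, sol.se, sol.loglik, sol.loglik_null,
                  int(rows["event"].sum()), rows["patient_id"].nunique(),
                  conc, sol.converged, sol.baseline_times, sol.baseline_cumhaz)


def pearson_chisq(table: np.ndarray | pd.DataFrame, correction: bool = False
                  ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table."""
    t = np.asarray(table, float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need a contingency table of at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cohens_kappa(confusion: np.ndarray | pd.DataFrame) -> float:
    """Cohen's kappa from a square confusion matrix:
    kappa = (p_o - p_e) / (1 - p_e) with chance agreement from the marginals."""
    m = np.asarray(confusion, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0):
        raise ValueError("negative counts")
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(m) / n
    pe = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / n**2)
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("degenerate marginals: chance agreement is 1")
    return float((po - pe) / (1 - pe))
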