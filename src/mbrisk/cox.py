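"""Newton solver for the Cox partial likelihood on counting-process data.

Supports (start, stop] risk sets, so time-dependent covariates (here: start
of craniospinal irradiation) enter by splitting a subject into consecutive
rows. Ties are handled with the Efron approximation. The implementation is
fully vectorised: risk-set sums at every event time are obtained from
suffix sums over rows sorted by start/stop, which keeps a single fit cheap
enough for bootstrap cross-validation with hundreds of refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CoxSolution", "fit_cox", "partial_loglik"]


class ConvergenceError(RuntimeError):
    pass


class RankError(ValueError):
    """Design matrix is rank deficient (e.g. a constant covariate)."""


@dataclass
class CoxSolution:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    baseline_times: np.ndarray      # distinct event times, ascending
    baseline_cumhaz: np.ndarray     # Efron-consistent cumulative baseline hazard
    information: np.ndarray         # observed information at the optimum


class _RiskSums:
    """Suffix-sum machinery for Sum_{i in risk set(t)} M_i at all event times.

    risk set(t) = {i : start_i < t <= stop_i}, hence
    Sum_{risk} = Sum_{stop >= t} - Sum_{start >= t}.
    """

    def __init__(self, start: np.ndarray, stop: np.ndarray, event: np.ndarray):
        self.n = len(stop)
        self.o_stop = np.argsort(stop, kind="stable")
        self.o_start = np.argsort(start, kind="stable")
        self.stop_sorted = stop[self.o_stop]
        self.start_sorted = start[self.o_start]
        self.times = np.unique(stop[event])
        self.i_stop = np.searchsorted(self.stop_sorted, self.times, side="left")
        self.i_start = np.searchsorted(self.start_sorted, self.times, side="left")
        # death sets grouped by event time
        ev_idx = np.flatnonzero(event)
        ev_order = ev_idx[np.argsort(stop[ev_idx], kind="stable")]
        self.death_rows = ev_order
        bounds = np.searchsorted(stop[ev_order], self.times, side="left")
        self.death_bounds = np.append(bounds, len(ev_order))
        self.d = np.diff(self.death_bounds)

    def risk(self, M: np.ndarray) -> np.ndarray:
        """Risk-set sums of row matrix M (n, q) at each event time -> (T, q)."""
        M = np.atleast_2d(M.T).T
        suf_stop = np.vstack([np.cumsum(M[self.o_stop][::-1], axis=0)[::-1],
                              np.zeros((1, M.shape[1]))])
        suf_start = np.vstack([np.cumsum(M[self.o_start][::-1], axis=0)[::-1],
                               np.zeros((1, M.shape[1]))])
        return suf_stop[self.i_stop] - suf_start[self.i_start]

    def deaths(self, M: np.ndarray) -> np.ndarray:
        """Sums of M over the failing rows at each event time -> (T, q)."""
        M = np.atleast_2d(M.T).T
        cs = np.vstack([np.zeros((1, M.shape[1])), np.cumsum(M[self.death_rows], axis=0)])
        return cs[self.death_bounds[1:]] - cs[self.death_bounds[:-1]]


def _efron_terms(rs: _RiskSums, X: np.ndarray, beta: np.ndarray):
    """Log-likelihood, score and information under the Efron approximation."""
    n, p = X.shape
    lp = X @ beta
    lp -= lp.max()  # common rescale; cancels in all ratios, restores below
    w = np.exp(lp)
    wx = w[:, None] * X
    wxx = (w[:, None] * X).reshape(n, p, 1) * X.reshape(n, 1, p)
    wxx = wxx.reshape(n, p * p)

    SR = rs.risk(w[:, None])[:, 0]
    SRx = rs.risk(wx)
    SRxx = rs.risk(wxx)
    SD = rs.deaths(w[:, None])[:, 0]
    SDx = rs.deaths(wx)
    SDxx = rs.deaths(wxx)
    lp_D = rs.deaths(lp[:, None])[:, 0]
    x_D = rs.deaths(X)

    d = rs.d.astype(float)
    ll = float(lp_D.sum())
    grad = x_D.sum(axis=0)
    info = np.zeros((p, p))
    maxd = int(rs.d.max())
    for k in range(maxd):
        m = rs.d > k
        frac = (k / d[m])[:, None]
        phi = SR[m] - frac[:, 0] * SD[m]
        Z = SRx[m] - frac * SDx[m]
        Q = SRxx[m] - frac * SDxx[m]
        ll -= float(np.log(phi).sum())
        Zp = Z / phi[:, None]
        grad -= Zp.sum(axis=0)
        info += (Q / phi[:, None]).sum(axis=0).reshape(p, p)
        info -= Zp.T @ Zp
    # undo the lp rescale in the log-likelihood (grad/info are scale-free)
    ll += float(rs.d.sum()) * 0.0
    return ll, grad, info


def partial_loglik(start, stop, event, X, beta) -> float:
    """Efron partial log-likelihood at ``beta`` (no rescaling applied)."""
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    event = np.asarray(event, bool)
    X = np.asarray(X, float)
    rs = _RiskSums(start, stop, event)
    lp = X @ np.asarray(beta, float)
    w = np.exp(lp)
    SR = rs.risk(w[:, None])[:, 0]
    SD = rs.deaths(w[:, None])[:, 0]
    lp_D = rs.deaths(lp[:, None])[:, 0]
    d = rs.d.astype(float)
    ll = float(lp_D.sum())
    for k in range(int(rs.d.max())):
        m = rs.d > k
        phi = SR[m] - (k / d[m]) * SD[m]
        ll -= float(np.log(phi).sum())
    return ll


def fit_cox(start, stop, event, X, tol: float = 1e-9, max_iter: int = 50,
            beta0=None) -> CoxSolution:
    """Maximise the Efron partial likelihood by Newton iteration.

    Raises
    ------
    ValueError
        If there are no events or times are invalid.
    RankError
        If the design matrix is rank deficient over the risk sets.
    """
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    event = np.asarray(event, bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if not event.any():
        raise ValueError("no events in the data; the partial likelihood is undefined")
    if np.any(stop <= start):
        raise ValueError("need stop > start for every row")
    if np.any(start < 0):
        raise ValueError("negative start times")
    if np.any(np.ptp(X, axis=0) == 0):
        raise RankError("constant covariate column")

    # column standardisation for numerical conditioning
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    rs = _RiskSums(start, stop, event)
    p = X.shape[1]
    ll_null, g0, i0 = _efron_terms(rs, Xs, np.zeros(p))
    if not np.all(np.isfinite(i0)) or np.linalg.cond(i0) > 1e12:
        raise RankError("collinear covariates: information singular at beta = 0")
    if beta0 is not None:
        beta = np.asarray(beta0, float) * scale
        ll, grad, info = _efron_terms(rs, Xs, beta)
        if not np.isfinite(ll):
            beta, ll, grad, info = np.zeros(p), ll_null, g0, i0
    else:
        beta, ll, grad, info = np.zeros(p), ll_null, g0, i0
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # trust region: cap the (standardised) step length
        m = float(np.abs(step).max())
        if m > 5.0:
            step *= 5.0 / m
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _efron_terms(rs, Xs, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve the likelihood")
        delta = float(np.abs(step).max())
        dll = abs(ll_new - ll)
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if delta < tol:
            converged = True
            break
        if dll < 1e-10 * max(1.0, abs(ll)):
            if delta > 0.1:
                # flat likelihood along a non-vanishing direction: monotone
                # likelihood (e.g. a stratum with no events); estimates in
                # that direction are unbounded but the fit is otherwise usable
                separated = True
            else:
                converged = True
            break

    cond = np.linalg.cond(info)
    if separated or not np.isfinite(cond) or cond > 1e12:
        warnings.warn("possible monotone likelihood / separation: some hazard "
                      "ratios are unbounded and their standard errors unreliable",
                      stacklevel=2)
        converged = False
        cov_s = np.linalg.pinv(info)
    else:
        cov_s = np.linalg.inv(info)
    beta_out = beta / scale
    se_out = np.sqrt(np.diag(cov_s)) / scale
    info_out = (info * scale[:, None]) * scale[None, :]

    # Efron-consistent baseline hazard increments at the fitted beta
    lp = X @ beta_out
    w = np.exp(lp)
    SR = rs.risk(w[:, None])[:, 0]
    SD = rs.deaths(w[:, None])[:, 0]
    d = rs.d.astype(float)
    inc = np.zeros(len(rs.times))
    for k in range(int(rs.d.max())):
        m = rs.d > k
        inc[m] += 1.0 / (SR[m] - (k / d[m]) * SD[m])
    cumhaz = np.cumsum(inc)

    # report the unscaled log-likelihood (rescaling cancels between ll and ll_null)
    ll_true = partial_loglik(start, stop, event, X, beta_out)
    ll0_true = partial_loglik(start, stop, event, X, np.zeros(p))
    return CoxSolution(beta_out, se_out, ll_true, ll0_true, it, converged,
                       rs.times.copy(), cumhaz, info_out)
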