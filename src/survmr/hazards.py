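"""Survival-regression engines.

Two estimators power the causal pipeline:

* :func:`fit_aalen` — Aalen's additive hazard model with time-varying
  coefficients, h(t | x) = sum_j x_j * alpha_j(t), estimated as cumulative
  regression functions B_j(t) = int_0^t alpha_j(s) ds.  The additive model is
  collapsible, which is what makes it suitable for instrumental-variable
  (Mendelian randomization) effect estimation on survival outcomes.
* :func:`fit_coxph` — Cox proportional hazards via the Breslow partial
  likelihood, used for the per-variant pleiotropy screen (a survival GWAS).

Both are deterministic and invariant to row permutation of their inputs.

Estimator details
-----------------
At each ordered event time t with at-risk design X_r(t) and event indicator
vector dN(t), the Aalen increment is the least-squares solve

    dB(t) = (X_r(t)' X_r(t))^{-1} X_r(t)' dN(t),

and the cumulative coefficient B(t) is the running sum of increments.  The
optional-variation covariance estimator accumulates

    dOmega(t) = X^-(t) diag(dN(t)) X^-(t)',   X^-(t) = (X_r'X_r)^{-1} X_r'.

Tied event times are handled within a single solve (dN carries the
multiplicity).  Estimation stops at the end of the identifiable range: the
last event time at which X_r'X_r is invertible at reciprocal condition number
1e-10; later events are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

RCOND_TOL = 1e-10


class SingularDesignError(np.linalg.LinAlgError):
    """At-risk design singular where an estimate is required."""


@dataclass
class AalenFit:
    """Result of an additive-hazard fit.

    Attributes
    ----------
    event_times : (T,) distinct event times inside the identifiable range.
    increments : (T, p) estimated coefficient increments dB(t).
    cumulative : (T, p) cumulative coefficients B(t) (step function; zero
        before the first event).
    increment_var : (T, p) diagonal of the optional-variation increment
        covariance dOmega(t).
    design_var : (T, p) diagonal of (X_r'X_r)^{-1}, the design-based scale of
        each increment's variance (used for inverse-variance test weights).
    n_at_risk : (T,) size of the at-risk set at each event time.
    names : covariate names, first entry the intercept.
    n_dropped_events : events beyond the identifiable range, excluded.
    """

    event_times: np.ndarray
    increments: np.ndarray
    cumulative: np.ndarray
    increment_var: np.ndarray
    design_var: np.ndarray
    n_at_risk: np.ndarray
    names: list
    n_dropped_events: int = 0

    @property
    def n_times(self) -> int:
        return len(self.event_times)

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "cumulative": self.cumulative.tolist(),
            "names": list(self.names),
            "n_dropped_events": int(self.n_dropped_events),
        }


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit (Breslow ties)."""

    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    names: list
    converged: bool
    n_events: int
    n_iter: int
    loglik: float
    separation: bool = False


def _as_design(design, names):
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (samples x covariates)")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def fit_aalen(design, time, event, names=None) -> AalenFit:
    """Fit Aalen's additive hazard model.

    Parameters
    ----------
    design
        (n, p) covariate matrix; must include an intercept column (a column
        of ones) for the baseline hazard.
    time, event
        Observed times (positive) and event indicators (1 = death observed).
    names
        Optional covariate names.

    Raises
    ------
    SingularDesignError
        If the at-risk design is singular already at the first event time.
    ValueError
        If there are no events.
    """
    X, names = _as_design(design, names)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    n, p = X.shape
    if d.sum() == 0:
        raise ValueError("no events: cannot fit an additive hazard model")
    if not np.any(np.all(X == 1.0, axis=0)):
        raise ValueError("design must include an intercept column of ones")

    order = np.argsort(t, kind="stable")
    Xs, ts, ds = X[order], t[order], d[order]

    # Suffix Gram matrices: G[i] = Xs[i:].T @ Xs[i:], built once in O(n p^2).
    outer = Xs[:, :, None] * Xs[:, None, :]
    G = np.cumsum(outer[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(ds == 1)
    ev_times = np.unique(ts[ev_idx])

    incs, variances, dvars, at_risk, times_kept = [], [], [], [], []
    n_dropped = 0
    stopped = False
    for et in ev_times:
        if stopped:
            n_dropped += int(np.sum((ts[ev_idx] == et)))
            continue
        start = np.searchsorted(ts, et, side="left")  # at-risk: time >= et
        XtX = G[start]
        # reciprocal condition number check on the at-risk Gram matrix
        sv = np.linalg.svd(XtX, compute_uv=False)
        if sv[-1] <= RCOND_TOL * sv[0] or sv[0] == 0:
            if not times_kept:
                raise SingularDesignError(
                    "at-risk design singular at the first event time"
                )
            stopped = True
            n_dropped += int(np.sum((ts[ev_idx] == et)))
            continue
        rows = ev_idx[(ts[ev_idx] == et)]
        # X^- columns for the event rows: (p, d_t)
        M = np.linalg.solve(XtX, Xs[rows].T)
        incs.append(M.sum(axis=1))
        variances.append((M * M).sum(axis=1))
        dvars.append(np.diag(np.linalg.inv(XtX)))
        at_risk.append(n - start)
        times_kept.append(et)

    inc = np.asarray(incs)
    return AalenFit(
        event_times=np.asarray(times_kept),
        increments=inc,
        cumulative=np.cumsum(inc, axis=0),
        increment_var=np.asarray(variances),
        design_var=np.asarray(dvars),
        n_at_risk=np.asarray(at_risk, dtype=int),
        names=names,
        n_dropped_events=n_dropped,
    )


def aalen_test(fit: AalenFit, index, weight: str = "invvar"):
    """Test H0: alpha_j(t) = 0 over the identifiable range.

    The statistic is U_j = sum_t K(t) dB_j(t) with variance
    sum_t K(t)^2 dOmega_jj(t), referred to a standard normal.  Weights:

    ``'invvar'`` (default)
        K_j(t) = 1 / [(X_r'X_r)^{-1}]_jj, the design-based information of the
        increment.  Reduces to the number at risk in an intercept-only model
        and is near-optimal against a time-constant alternative, which is the
        effect the causal pipeline screens for.
    ``'atrisk'``
        K(t) = number at risk.
    ``'flat'``
        K = 1; U_j is the terminal cumulative coefficient.  Heavily
        influenced by late, small-risk-set increments, so mainly of
        diagnostic interest.

    Any uniform rescaling of K leaves the standardized statistic unchanged.

    Returns
    -------
    (stat, z, p) : the weighted sum U_j, its z-score and two-sided p-value.
    """
    if isinstance(index, str):
        index = fit.names.index(index)
    if fit.n_times < 1:
        raise ValueError("fit has no event times")
    if weight == "invvar":
        K = 1.0 / fit.design_var[:, index]
    elif weight == "atrisk":
        K = fit.n_at_risk.astype(float)
    elif weight == "flat":
        K = np.ones(fit.n_times)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    U = float(np.sum(K * fit.increments[:, index]))
    var = float(np.sum(K**2 * fit.increment_var[:, index]))
    if var <= 0:
        raise ZeroDivisionError("zero variance for the tested covariate")
    z = U / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return U, z, max(p, np.finfo(float).tiny)


def nelson_aalen(time, event):
    """Nelson–Aalen cumulative hazard estimator (ties pooled).

    Returns (event_times, cumulative_hazard); the intercept-only Aalen fit
    reduces to this exactly.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    ev_times = np.unique(t[d == 1])
    inc = []
    for et in ev_times:
        at_risk = np.sum(t >= et)
        deaths = np.sum((t == et) & (d == 1))
        inc.append(deaths / at_risk)
    return ev_times, np.cumsum(inc)


def _cox_loglik_grad_hess(beta, Xs, ds, ties_last):
    """Breslow log partial likelihood with gradient and Hessian.

    ``Xs`` is sorted by descending time so risk sets are prefixes;
    ``ties_last[i]`` marks the last row of each tied time block.
    """
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(Xs * w[:, None], axis=0)
    outer = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum(outer * w[:, None, None], axis=0)

    # risk set of an event = prefix up to the END of its tie block; each
    # event contributes one copy of its block's S-terms (Breslow)
    ends = np.flatnonzero(ties_last)
    ev = np.flatnonzero(ds == 1)
    if len(ev) == 0:
        return -np.inf, np.zeros(len(beta)), np.zeros((len(beta), len(beta)))
    j = ends[np.searchsorted(ends, ev)]
    s0 = S0[j]
    mu = S1[j] / s0[:, None]
    ll = float(eta[ev].sum() - np.log(s0).sum())
    grad = Xs[ev].sum(axis=0) - mu.sum(axis=0)
    hess = -((S2[j] / s0[:, None, None]).sum(axis=0) - mu.T @ mu)
    return ll, grad, hess


def fit_coxph(design, time, event, names=None, max_iter=50, tol=1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model (Breslow ties, Newton–Raphson).

    The design must not contain an intercept (it is absorbed by the baseline
    hazard) nor any constant column.  Convergence is declared when the
    relative change in log partial likelihood falls below ``tol``; steps are
    halved whenever the likelihood would decrease.  Monotone likelihood
    (perfect separation) is flagged via ``separation`` and leaves
    ``converged`` False.
    """
    X, names = _as_design(design, names)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if d.sum() == 0:
        raise ValueError("no events: Cox partial likelihood undefined")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate in Cox design (intercept is implicit)")

    # standardize for numerical stability; back-transform at the end
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd

    order = np.argsort(-t, kind="stable")
    Zs, ts, ds = Z[order], t[order], d[order]
    ties_last = np.empty(len(ts), dtype=bool)
    ties_last[:-1] = ts[:-1] != ts[1:]
    ties_last[-1] = True

    beta = np.zeros(Z.shape[1])
    ll, grad, hess = _cox_loglik_grad_hess(beta, Zs, ds, ties_last)
    converged, separation, it = False, False, 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("singular information matrix in Cox fit") from exc
        # step halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _cox_loglik_grad_hess(cand, Zs, ds, ties_last)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll_prev, ll = cand, ll, ll_new
        grad, hess = g_new, h_new
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
        if np.max(np.abs(beta)) > 50:
            separation = True
            break

    cov = np.linalg.inv(-hess)
    beta_x = beta / sd
    se_x = np.sqrt(np.diag(cov)) / sd
    z = beta_x / se_x
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        beta=beta_x,
        se=se_x,
        wald_p=np.maximum(p, np.finfo(float).tiny),
        names=names,
        converged=converged and not separation,
        n_events=int(d.sum()),
        n_iter=it,
        loglik=float(ll),
        separation=separation,
    )
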