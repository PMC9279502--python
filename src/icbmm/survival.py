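"""Time-to-progression endpoints and survival statistics.

Implements the survival layer of the analysis: real-world time to progression
(TTP) construction with its censoring rules, the Kaplan-Meier product-limit
estimator, the k-group log-rank test, and a Cox proportional-hazards fitter
using the Breslow approximation for tied event times with an optional ridge
penalty (the penalized fit is what the multimodal resampling model uses).

The Cox partial log-likelihood with Breslow ties is

    l(b) = sum_j [ s_j' b - d_j * log( sum_{i in R(t_j)} exp(x_i' b) ) ]

over distinct event times t_j with d_j events, event-covariate sum s_j, and
risk set R(t_j) = {i : t_i >= t_j}; censored subjects tied with an event time
remain at risk for it. The ridge objective subtracts (alpha/2)*||b||^2 and is
maximized by Newton-Raphson with step-halving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "derive_ttp",
    "km_estimate",
    "logrank_test",
    "fit_cox_breslow",
    "cox_score_test",
]

MIN_FOLLOWUP_DAYS = 90.0

_NONPROGRESSION_STOP_REASONS = {"adverse_event", "non_compliance", "other"}


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: int
    group: str | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


def derive_ttp(patient_id: str, *, treatment_start: float,
               progression_day: float | None = None,
               treatment_stop_day: float | None = None,
               stop_reason: str | None = None,
               last_encounter_day: float | None = None) -> SurvivalRecord | None:
    """Construct a TTP record from per-patient clinical event days.

    Event = 1 at the first progression after treatment start. Otherwise the
    patient is censored: at treatment stop when treatment ended for a
    non-progression reason (adverse event, non-compliance, other), else at the
    last known clinical encounter. Patients with no progression and less than
    90 days of follow-up are ineligible and return ``None``.
    """
    if progression_day is not None:
        if progression_day < treatment_start:
            raise ValueError(f"{patient_id}: progression precedes treatment start")
        return SurvivalRecord(patient_id, progression_day - treatment_start, 1)
    if treatment_stop_day is not None and (
            stop_reason is None or stop_reason in _NONPROGRESSION_STOP_REASONS):
        t = treatment_stop_day - treatment_start
    elif last_encounter_day is not None:
        t = last_encounter_day - treatment_start
    else:
        raise ValueError(f"{patient_id}: no censoring anchor available")
    if t < MIN_FOLLOWUP_DAYS:
        return None  # ineligible: <90 days follow-up and no progression
    return SurvivalRecord(patient_id, t, 0)


def _as_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if np.any(time <= 0):
        raise ValueError("all times must be > 0")
    return time, event


def km_estimate(time, event) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier product-limit estimator.

    Returns (table, median) where table has one row per distinct event time
    with columns t, at_risk, events, survival; median is the smallest t with
    S(t) <= 0.5, or NaN if the curve never reaches 0.5.
    """
    time, event = _as_arrays(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = time.size
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += int(event[j])
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    table = pd.DataFrame(rows, columns=["t", "at_risk", "events", "survival"])
    median = float("nan")
    reached = table[table["survival"] <= 0.5]
    if not reached.empty:
        median = float(reached["t"].iloc[0])
    return table, median


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    time, event = _as_arrays(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    g = np.searchsorted(labels, group)
    event_times = np.unique(time[event == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_gt = np.bincount(g[at_risk], minlength=k).astype(float)
        d_gt = np.bincount(g[(time == t) & (event == 1)], minlength=k).astype(float)
        obs += d_gt
        exp += d_t * n_gt / n_t
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1.0)
            p_g = n_gt / n_t
            var += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    diff = (obs - exp)[:-1]
    v = var[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class CoxFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    log_partial_likelihood: float
    n_iterations: int
    converged: bool
    ridge_alpha: float

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        """exp(beta) with Wald 95% CI and two-sided p-values."""
        beta = self.coefficients
        se = self.standard_errors
        z = beta / se
        return pd.DataFrame({
            "coef": beta,
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - 1.96 * se),
            "hr_ci_high": np.exp(beta + 1.96 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        })

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.coefficients.index)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coefficients.to_numpy()


def _breslow_ll_grad_hess(beta, X, time, event):
    """Breslow partial log-likelihood, gradient and Hessian (unpenalized)."""
    eta = X @ beta
    m = eta.max()  # guard exp overflow; re-added inside log below
    w = np.exp(eta - m)
    # sort descending by time so suffix sums become prefix cumsums
    order = np.argsort(-time, kind="stable")
    Xs, ts, es, ws = X[order], time[order], event[order], w[order]
    cum_w = np.cumsum(ws)
    cum_xw = np.cumsum(Xs * ws[:, None], axis=0)
    k = X.shape[1]
    cum_xxw = np.cumsum(Xs[:, :, None] * Xs[:, None, :] * ws[:, None, None], axis=0)

    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    n = len(ts)
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            j += 1
        ev = es[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            # risk set = all with time >= t = rows 0..j-1 in descending order
            S0 = cum_w[j - 1]
            S1 = cum_xw[j - 1]
            S2 = cum_xxw[j - 1]
            s_x = Xs[i:j][ev].sum(axis=0)
            ll += s_x @ beta - d * (np.log(S0) + m)
            grad += s_x - d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j
    return ll, grad, hess


def fit_cox_breslow(X, time, event, ridge_alpha: float = 0.0,
                    max_iter: int = 100, tol_ll: float = 1e-9,
                    tol_grad: float = 1e-8) -> CoxFit:
    """Fit a Cox model with Breslow tie handling and an optional ridge penalty.

    Parameters
    ----------
    X : DataFrame or array, subjects x covariates. Covariates are used as
        provided (no internal centering or scaling); a zero-variance covariate
        is an error.
    ridge_alpha : L2 penalty weight; the objective is the Breslow partial
        log-likelihood minus (ridge_alpha/2)*||beta||^2. Standard errors come
        from the observed information of the penalized objective.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[0] == 1 and Xa.shape[1] > 1 and np.asarray(time).size == Xa.shape[1]:
            Xa = Xa.T
        names = [f"x{i}" for i in range(Xa.shape[1])]
    time, event = _as_arrays(time, event)
    if not np.all(np.isfinite(Xa)):
        raise ValueError("covariates must be finite")
    if int(event.sum()) < 1:
        raise ValueError("need at least one event")
    variances = Xa.var(axis=0)
    if np.any(variances == 0):
        bad = [names[i] for i in np.where(variances == 0)[0]]
        raise ValueError(f"constant covariates: {bad}")
    if ridge_alpha < 0:
        raise ValueError("ridge_alpha must be >= 0")

    k = Xa.shape[1]
    beta = np.zeros(k)
    ll, grad, hess = _breslow_ll_grad_hess(beta, Xa, time, event)
    ll_pen = ll - 0.5 * ridge_alpha * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = grad - ridge_alpha * beta
        H = hess - ridge_alpha * np.eye(k)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix (possible separation)")
        # step-halving line search on the penalized objective
        new_beta = beta + step
        for _ in range(30):
            ll_new, grad_new, hess_new = _breslow_ll_grad_hess(new_beta, Xa, time, event)
            ll_pen_new = ll_new - 0.5 * ridge_alpha * new_beta @ new_beta
            if ll_pen_new >= ll_pen - 1e-14:
                break
            step = step / 2.0
            new_beta = beta + step
        if np.max(np.abs(new_beta)) > 50:
            raise ValueError("diverging coefficients: possible complete separation")
        delta_ll = abs(ll_pen_new - ll_pen)
        beta, ll, grad, hess = new_beta, ll_new, grad_new, hess_new
        ll_pen = ll_pen_new
        g = grad - ridge_alpha * beta
        if delta_ll < tol_ll or np.max(np.abs(g)) < tol_grad:
            converged = True
            break
    if not converged:
        warnings.warn("Cox fit did not converge within max_iter", RuntimeWarning)
    H_pen = hess - ridge_alpha * np.eye(k)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(np.linalg.inv(-H_pen)))
    if not np.all(np.isfinite(se)):
        raise ValueError("non-finite standard errors: possible separation or "
                         "degenerate design")
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        log_partial_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
        ridge_alpha=float(ridge_alpha),
    )


def breslow_partial_loglik(beta, X, time, event) -> float:
    """Breslow partial log-likelihood at a given beta (no penalty)."""
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    time, event = _as_arrays(time, event)
    ll, _, _ = _breslow_ll_grad_hess(beta, Xa, time, event)
    return float(ll)


def cox_score_test(x, time, event) -> tuple[float, float]:
    """Score test of beta = 0 for a single covariate (no penalty).

    Returns (chi-square, p). With a binary group indicator and no tied event
    times this equals the two-group log-rank test.
    """
    Xa = np.asarray(x, dtype=float)[:, None]
    time, event = _as_arrays(time, event)
    _, grad, hess = _breslow_ll_grad_hess(np.zeros(1), Xa, time, event)
    chi2 = float(grad[0] ** 2 / (-hess[0, 0]))
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, p
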