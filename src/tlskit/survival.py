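"""Survival-analysis substrate: Kaplan-Meier, log-rank, Cox PH, BH-FDR.

The Cox partial-likelihood maximizer is implemented here directly (Newton-
Raphson with Efron tie correction) because the genome-wide interaction screen
needs tens of thousands of small fits; ``lifelines`` serves as an independent
cross-check in the test suite, never as the screen's engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "bh_fdr",
]


@dataclass
class KMResult:
    """Product-limit estimate: right-continuous step function S(t)."""

    times: np.ndarray          # event/censor times in ascending order
    survival: np.ndarray       # S(t) just after each time
    median: float              # first t with S(t) <= 0.5, NaN if never reached
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    n: int = 0
    n_events: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.covariates,
        )


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no subjects")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("survival times must be positive and finite")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def km_estimate(time, event) -> KMResult:
    """Kaplan-Meier product-limit estimate with median survival.

    The median is the first observed time at which S(t) drops to 0.5 or
    below; with no events (or S never reaching 0.5) it is NaN.
    """
    time, event = _check_surv(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # lifelines includes t=0 with S=1; keep strictly positive knots
    keep = times > 0
    times, surv = times[keep], surv[keep]
    below = np.nonzero(surv <= 0.5)[0]
    median = float(times[below[0]]) if below.size else float("nan")
    return KMResult(times=times, survival=surv, median=median, n=time.size)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    With no events at all the test is undefined; returns (0, 1) with a
    warning rather than failing.
    """
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"exactly 2 non-empty groups required, got {labels.size}")
    if event.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, p=1")
        return 0.0, 1.0
    a = group == labels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------

def _cox_nll_grad_hess(beta, X, time, event):
    """Negative log partial likelihood with Efron tie correction.

    Data must be pre-sorted by time descending so that the risk set at each
    event time is a prefix of the arrays.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # prefix sums: risk set for time t = all rows with time >= t = rows [0..k]
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t = time[i]
        while j < n and time[j] == t:
            j += 1
        dead = np.nonzero(event[i:j])[0] + i
        d = dead.size
        if d > 0:
            k = j - 1  # last index in risk set
            s0_r, s1_r, s2_r = cw[k], cwx[k], cwxx[k]
            wd = w[dead]
            s0_d = wd.sum()
            s1_d = wx[dead].sum(axis=0)
            s2_d = wxx[dead].sum(axis=0)
            nll -= eta[dead].sum()
            for ell in range(d):
                f = ell / d
                s0 = s0_r - f * s0_d
                s1 = s1_r - f * s1_d
                s2 = s2_r - f * s2_d
                nll += np.log(s0)
                grad -= s1 / s0
                hess += s2 / s0 - np.outer(s1, s1) / s0**2
        i = j
    grad += X[event == 1].sum(axis=0)
    return nll, -grad, hess  # grad of nll = -(score)


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    data : DataFrame with one row per subject.
    covariates : columns to enter the linear predictor.
    tol : sup-norm of the score at which iteration stops.

    Efron's correction handles tied event times.  Monotone likelihood
    (complete separation) is reported via ``converged=False`` together with
    a warning -- never as a silently huge coefficient.
    """
    time, event = _check_surv(data[duration_col], data[event_col])
    X = data[covariates].to_numpy(dtype=float)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(covariates, sd) if s == 0]
        raise ValueError(f"constant covariate(s): {bad}")

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    p = X.shape[1]
    beta = np.zeros(p)
    nll, g, H = _cox_nll_grad_hess(beta, Xs, ts, es)
    converged = False
    diverged = False
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the objective stops increasing
        lam, stalled = 1.0, True
        floor = 1e-12 * (1.0 + abs(nll))
        for _ in range(30):
            cand = beta - lam * step
            nll_new, g_new, H_new = _cox_nll_grad_hess(cand, Xs, ts, es)
            if nll_new <= nll + floor:
                beta, nll, g, H = cand, nll_new, g_new, H_new
                stalled = False
                break
            lam /= 2
        if stalled:
            # objective change below the floating-point floor: at the optimum
            converged = bool(np.max(np.abs(g)) < 1e-4)
            break
        if np.max(np.abs(beta)) > 50:
            diverged = True
            break  # monotone likelihood: coefficient escaping to infinity
    if not diverged and not converged:
        converged = bool(np.max(np.abs(g)) < max(tol, 1e-6))

    cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    # monotone likelihood flattens the gradient at a huge coefficient with
    # an even larger SE; flag it rather than returning a silently absurd HR
    if np.any((np.abs(beta) > 10) & (se > np.abs(beta))):
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / separation)"
        )
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(
        covariates=list(covariates),
        coef=beta,
        se=se,
        hr=np.exp(np.clip(beta, -700, 700)),
        ci_low=np.exp(np.clip(beta - 1.96 * se, -700, 700)),
        ci_high=np.exp(np.clip(beta + 1.96 * se, -700, 700)),
        p=pvals,
        log_likelihood=-nll,
        converged=converged,
        n=len(time),
        n_events=int(event.sum()),
    )


def cox_score_test(data, covariate, duration_col="time_months", event_col="event") -> tuple[float, float]:
    """Score (Rao) test of beta=0 for a single covariate Cox model.

    On tie-free data with a binary covariate this equals the log-rank
    chi-square statistic.
    """
    time, event = _check_surv(data[duration_col], data[event_col])
    X = data[[covariate]].to_numpy(dtype=float)
    order = np.argsort(-time, kind="stable")
    _, g, H = _cox_nll_grad_hess(np.zeros(1), X[order], time[order], event[order])
    u = -g[0]  # score = -d(nll)/dbeta at 0
    stat = u**2 / H[0, 0]
    return float(stat), float(stats.chi2.sf(stat, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]
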