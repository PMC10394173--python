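"""Copy-number association with TLS status.

Two analyses: a per-gene empirical-Bayes moderated two-sample t-test
(variance shrinkage toward a pooled prior, limma-style, with BH-FDR
q-values) and per-group gain/loss frequency profiles on the GISTIC scale.

The moderated-t hyperparameters (prior df d0 and prior variance s0^2) are
estimated by moment-matching the log sample variances against scaled-F
theory: if s_g^2 ~ s0^2 * F(d_g, d0) then

    E[log s_g^2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
    Var[log s_g^2] = psi'(d/2) + psi'(d0/2)

so d0 solves psi'(d0/2) = Var[e_g] with e_g = log s_g^2 - psi(d/2) + log(d/2),
and s0^2 = exp(mean(e_g) + psi(d0/2) - log(d0/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .survival import bh_fdr

__all__ = ["ModeratedTestResult", "moderated_t_test", "cna_frequency"]


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame   # per gene: delta, s, t, p, q
    prior_df: float       # d0 (may be inf)
    prior_var: float      # s0^2


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 (Newton, as in the standard EB recipe)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from per-gene variances.

    Zero variances are offset to 1e-5 times the median before taking logs
    (never dividing by zero); if the log-variances are underdispersed
    relative to chi-square theory the prior df is infinite and s0^2 is the
    arithmetic mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    m = np.median(s2)
    if m == 0:
        m = 1.0
    s2c = np.maximum(s2, 1e-5 * m)
    z = np.log(s2c)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.mean(s2c))
    d0 = 2 * _trigamma_inverse(float(evar))
    s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0sq


def moderated_t_test(
    cna: pd.DataFrame,
    labels: pd.Series,
    prior_df: float | None = None,
) -> ModeratedTestResult:
    """Per-gene moderated two-sample t comparing TLS-high vs TLS-low.

    Parameters
    ----------
    cna : genes x samples matrix (GISTIC integers or log-ratios).
    labels : per-sample binary labels aligned with the columns (1 = high).
    prior_df : override the estimated prior df d0; 0 recovers the ordinary
        equal-variance two-sample t exactly, ``inf`` shrinks every gene's
        variance fully to s0^2.

    Returns per-gene mean difference (high - low), pooled residual SD,
    moderated t, p (t distribution with d0 + d_g df) and BH q.
    """
    labels = labels.reindex(cna.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    hi = cna.loc[:, labels == 1].to_numpy(dtype=float)
    lo = cna.loc[:, labels == 0].to_numpy(dtype=float)
    n1, n2 = hi.shape[1], lo.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    df = n1 + n2 - 2

    delta = hi.mean(axis=1) - lo.mean(axis=1)
    ss = (hi - hi.mean(axis=1, keepdims=True)) ** 2
    ss2 = (lo - lo.mean(axis=1, keepdims=True)) ** 2
    s2 = (ss.sum(axis=1) + ss2.sum(axis=1)) / df

    d0, s0sq = estimate_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)  # s0^2 stays data-driven; unused when d0=0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
    # total df capped at the pooled residual df: the prior cannot carry
    # more information than the dataset it was estimated from
    total_df = min(d0 + df, df * len(s2))

    sem = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sem > 0, delta / np.where(sem > 0, sem, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=total_df)
    q = bh_fdr(p)

    table = pd.DataFrame(
        {"delta": delta, "s": np.sqrt(s2), "t": t, "p": p, "q": q},
        index=cna.index,
    )
    return ModeratedTestResult(table=table, prior_df=d0, prior_var=s0sq)


def cna_frequency(
    cna: pd.DataFrame,
    labels: pd.Series,
    gain_threshold: float = 1.0,
    loss_threshold: float = -1.0,
) -> pd.DataFrame:
    """Per-gene per-group gain and loss proportions.

    gain = fraction of the group's samples with value >= gain_threshold,
    loss = fraction with value <= loss_threshold (stored as a magnitude in
    [0,1]; the plotting convention applies the negative sign on output).
    """
    if gain_threshold <= loss_threshold:
        raise ValueError("gain_threshold must exceed loss_threshold")
    labels = labels.reindex(cna.columns)
    out = {}
    for grp, name in ((1, "high"), (0, "low")):
        sub = cna.loc[:, labels == grp].to_numpy(dtype=float)
        if sub.shape[1] == 0:
            raise ValueError(f"group {name!r} is empty")
        out[f"gain_{name}"] = (sub >= gain_threshold).mean(axis=1)
        out[f"loss_{name}"] = (sub <= loss_threshold).mean(axis=1)
    return pd.DataFrame(out, index=cna.index)
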