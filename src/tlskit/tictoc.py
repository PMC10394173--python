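"""Genome-wide TLS x CNA Cox interaction screen and TICTOC classification.

For every gene a Cox proportional-hazards model with covariates
{z(TLS), CNA_g, z(TLS) * CNA_g} is fitted against overall survival; the
interaction coefficient measures whether the gene's copy-number state
abrogates (HR_int > 1 for gains) or preserves the protective TLS effect.
BH-FDR is computed once over all successfully fitted genes.  TICTOC genes
are the screen hits whose copy-number state also drives their own
expression (|Pearson r| above threshold), optionally annotated with
druggability tiers from a static gene -> category table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .survival import bh_fdr, cox_fit, km_estimate, logrank_test

__all__ = [
    "interaction_screen",
    "cna_expr_correlation",
    "classify_tictoc",
    "stratified_tls_survival",
]


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=0)


def interaction_screen(
    cna: pd.DataFrame,
    tls: pd.Series,
    clinical: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    use_labels: bool = False,
) -> pd.DataFrame:
    """Per-gene Cox interaction screen of TLS benefit against CNA state.

    Parameters
    ----------
    cna : genes x samples CNA matrix.
    tls : per-sample TLS signature score (entered z-scored and continuous
        by default; ``use_labels=True`` enters it as given, for the binary
        high/low sensitivity analysis).
    clinical : indexed by sample id with duration and event columns.

    Returns a table with one row per gene: beta_int, hr_int, p_int, q_int,
    beta_tls, beta_cna, direction (gain/loss by the gene's dominant
    alteration sign in the cohort), and a status column.  Genes that are
    constant or whose fit does not converge are flagged and excluded from
    the FDR computation; the screen output is independent of gene order.
    """
    samples = list(cna.columns)
    if not set(samples) <= set(clinical.index) or not set(samples) <= set(tls.index):
        raise ValueError("sample ids misaligned between CNA, TLS, and clinical inputs")
    clin = clinical.loc[samples]
    if clin[event_col].sum() < 20:
        raise ValueError("need at least 20 events for a genome-wide screen")
    z = tls.loc[samples] if use_labels else _zscore(tls.loc[samples])

    base = pd.DataFrame(
        {
            "time": clin[duration_col].to_numpy(dtype=float),
            "event": clin[event_col].to_numpy(dtype=int),
            "tls": z.to_numpy(dtype=float),
        },
        index=samples,
    )

    rows = []
    for gene in cna.index:
        g = cna.loc[gene, samples].to_numpy(dtype=float)
        rec = {
            "gene_id": gene,
            "beta_int": np.nan, "hr_int": np.nan, "p_int": np.nan,
            "beta_tls": np.nan, "beta_cna": np.nan, "se_int": np.nan,
            "direction": "gain" if (g > 0).sum() >= (g < 0).sum() else "loss",
            "status": "ok",
        }
        if np.std(g) == 0:
            rec["status"] = "constant_cna"
            rows.append(rec)
            continue
        df = base.assign(cna=g, inter=base["tls"].to_numpy() * g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = cox_fit(df, ["tls", "cna", "inter"],
                              duration_col="time", event_col="event")
            except (ValueError, np.linalg.LinAlgError):
                rec["status"] = "fit_error"
                rows.append(rec)
                continue
        if not fit.converged:
            rec["status"] = "not_converged"
            rows.append(rec)
            continue
        i = fit.covariates.index("inter")
        rec.update(
            beta_int=fit.coef[i], hr_int=fit.hr[i], p_int=fit.p[i],
            se_int=fit.se[i],
            beta_tls=fit.coef[fit.covariates.index("tls")],
            beta_cna=fit.coef[fit.covariates.index("cna")],
        )
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("gene_id")
    ok = out["status"] == "ok"
    out["q_int"] = np.nan
    if ok.any():
        out.loc[ok, "q_int"] = bh_fdr(out.loc[ok, "p_int"].to_numpy())
    return out


def cna_expr_correlation(
    cna: pd.DataFrame, expr: pd.DataFrame, method: str = "pearson"
) -> pd.Series:
    """Correlation of each gene's CNA with its own expression.

    Computed over the shared samples for genes present in both matrices;
    genes with a constant vector get NaN (correlation undefined).
    """
    shared_samples = [s for s in cna.columns if s in expr.columns]
    genes = [g for g in cna.index if g in expr.index]
    if not genes or len(shared_samples) < 3:
        raise ValueError("need shared genes and at least 3 shared samples")
    r = {}
    for g in genes:
        a = cna.loc[g, shared_samples].to_numpy(dtype=float)
        b = expr.loc[g, shared_samples].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            r[g] = np.nan
            continue
        if method == "pearson":
            r[g] = stats.pearsonr(a, b).statistic
        elif method == "spearman":
            r[g] = stats.spearmanr(a, b).statistic
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.Series(r, name="expr_corr")


def classify_tictoc(
    records: pd.DataFrame,
    expr_corr: pd.Series,
    r_threshold: float = 0.3,
    q_threshold: float = 0.25,
    drug_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select TICTOC genes from the screen output.

    Gains: HR_int > 1 and q < q_threshold and r > r_threshold.
    Losses: HR_int < 1 and q < q_threshold and r > r_threshold.
    HR_int exactly 1 belongs to neither arm.  ``drug_table`` (columns
    gene_id, category) annotates druggability; genes absent from it are
    'unannotated'.  An empty selection is a valid result.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["hr_int", "q_int", "expr_corr", "direction", "druggability"]
        )
    rec = records.copy()
    rec["expr_corr"] = expr_corr.reindex(rec.index)
    eligible = (
        (rec["status"] == "ok")
        & (rec["q_int"] < q_threshold)
        & (rec["expr_corr"] > r_threshold)
    )
    gain = eligible & (rec["hr_int"] > 1)
    loss = eligible & (rec["hr_int"] < 1)
    sel = rec.loc[gain | loss, ["hr_int", "q_int", "expr_corr"]].copy()
    sel["direction"] = np.where(rec.loc[sel.index, "hr_int"] > 1, "gain", "loss")
    if drug_table is not None:
        lookup = drug_table.set_index("gene_id")["category"]
        sel["druggability"] = lookup.reindex(sel.index).fillna("unannotated")
    else:
        sel["druggability"] = "unannotated"
    return sel.sort_values("q_int")


def stratified_tls_survival(
    tls_labels: pd.Series,
    cna_values: pd.Series,
    clinical: pd.DataFrame,
    strat_threshold: float = 1.0,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> dict:
    """TLS survival benefit within CNA strata (amplified vs not).

    Stratum 'amplified' = samples with CNA >= strat_threshold, 'wild_type'
    otherwise.  Within each stratum: KM curves per TLS group, log-rank
    TLS-high vs low, and a univariate Cox fit of the TLS label.  A stratum
    with no events (or only one TLS group) is reported with a warning and
    carries no p-value.
    """
    samples = list(tls_labels.index)
    amp = cna_values.loc[samples] >= strat_threshold
    if amp.all() or (~amp).all():
        raise ValueError("degenerate stratification: one stratum is empty")
    out = {}
    for name, sel in (("amplified", amp), ("wild_type", ~amp)):
        ids = [s for s in samples if sel.loc[s]]
        clin = clinical.loc[ids]
        lab = tls_labels.loc[ids]
        entry = {"n": len(ids), "n_events": int(clin[event_col].sum())}
        entry["km"] = {
            str(g): km_estimate(
                clin.loc[lab == g, duration_col], clin.loc[lab == g, event_col]
            )
            for g in sorted(lab.unique())
        }
        if entry["n_events"] == 0 or lab.nunique() < 2:
            warnings.warn(f"stratum {name!r}: no events or a single TLS group; no test")
            entry["logrank_p"] = None
        else:
            chi2, p = logrank_test(clin[duration_col], clin[event_col], lab)
            entry["logrank_chi2"], entry["logrank_p"] = chi2, p
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = cox_fit(
                        clin.assign(tls=lab.to_numpy(dtype=float)), ["tls"],
                        duration_col=duration_col, event_col=event_col,
                    )
                    entry["tls_hr"] = float(fit.hr[0])
                    entry["tls_ci"] = (float(fit.ci_low[0]), float(fit.ci_high[0]))
                except ValueError:
                    entry["tls_hr"] = None
        out[name] = entry
    return out
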