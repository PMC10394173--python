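"""Radiomic TLS score (RPV): standardization, Spearman pre-filter, LASSO.

The score is a sparse linear model of standardized radiomic features
trained against the transcriptomic TLS signature: features are centered
and scaled with training-cohort factors (the same factors are applied to
any test cohort), weakly TLS-correlated features (|Spearman rho| above a
threshold, 0.1 for the ovarian preset, 0.3 for the lung preset) enter a
LASSO whose penalty is chosen at minimal mean cross-validated MSE.  For
bilateral cases the mass with the higher score represents the case.

The published ovarian three-feature model ships as a packaged constant
(models/ov_tls_rpv_published.json): 0.109 * GLCM_Entrop_25HUgl
+ 0.0557 * GLCM_InfCo1_HHL_25HUgl - 0.109 * GLCM_sumEnt_HLL_25HUgl on
standardized features, intercept 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .scoring import dichotomize_scores
from .survival import cox_fit, km_estimate, logrank_test

__all__ = [
    "StandardizationFactors",
    "RpvModel",
    "standardize",
    "apply_factors",
    "prefilter_spearman",
    "lasso_cv",
    "rpv_score",
    "aggregate_bilateral",
    "rpv_survival_report",
    "load_published_model",
]


@dataclass
class StandardizationFactors:
    mean: pd.Series
    sd: pd.Series  # zero-SD features are dropped before construction

    @property
    def features(self) -> list[str]:
        return list(self.mean.index)

    def checksum(self) -> float:
        return float(self.mean.sum() + self.sd.sum())


@dataclass
class RpvModel:
    features: list[str]
    coefficients: np.ndarray
    intercept: float = 0.0
    penalty: float | None = None
    cv_folds: int | None = None
    prefilter_threshold: float | None = None
    cv_curve: pd.DataFrame | None = None  # lambda -> mean held-out MSE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != self.coefficients.size:
            raise ValueError("features and coefficients length mismatch")

    def to_json(self, path):
        payload = {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "cv_folds": self.cv_folds,
            "prefilter_threshold": self.prefilter_threshold,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RpvModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=d.get("intercept", 0.0),
            penalty=d.get("penalty"),
            cv_folds=d.get("cv_folds"),
            prefilter_threshold=d.get("prefilter_threshold"),
            metadata=d.get("metadata", {}),
        )


def load_published_model() -> RpvModel:
    """The published ovarian three-feature radiomic TLS model."""
    ref = resources.files("tlskit") / "models" / "ov_tls_rpv_published.json"
    with resources.as_file(ref) as path:
        return RpvModel.from_json(path)


def standardize(train: pd.DataFrame) -> tuple[StandardizationFactors, pd.DataFrame]:
    """Center/scale training features; constant features dropped with a warning."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    bad = sd.index[sd == 0].tolist()
    if bad:
        warnings.warn(f"dropping constant feature(s): {bad}")
    keep = sd.index[sd > 0]
    factors = StandardizationFactors(mean=mean[keep], sd=sd[keep])
    return factors, (train[keep] - mean[keep]) / sd[keep]


def apply_factors(test: pd.DataFrame, factors: StandardizationFactors) -> pd.DataFrame:
    """Transform a test cohort with training factors only (never refit)."""
    missing = [f for f in factors.features if f not in test.columns]
    if missing:
        raise ValueError(f"test cohort missing feature(s): {missing}")
    cols = factors.features
    return (test[cols] - factors.mean) / factors.sd


def prefilter_spearman(
    features: pd.DataFrame, target: pd.Series, threshold: float = 0.1
) -> list[str]:
    """Keep features with |Spearman rho| (average ranks for ties) > threshold.

    Constant features have undefined rho and are excluded.
    """
    target = target.loc[features.index]
    kept = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0 or target.std() == 0:
            continue
        rho = stats.spearmanr(x, target.to_numpy(dtype=float)).statistic
        if np.isfinite(rho) and abs(rho) > threshold:
            kept.append(col)
    return kept


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient: max|X'(y - ybar)|/n."""
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def lasso_cv(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 10,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
) -> RpvModel:
    """LASSO over a penalty grid; lambda chosen at minimal mean CV MSE.

    Objective: (1/2n) ||y - Xw - b||^2 + lambda ||w||_1 (coordinate
    descent).  Default grid: 100 log-spaced penalties from lambda_max down
    to 1e-4 * lambda_max.  Fold assignment is seeded, so the fit is
    deterministic; the model is refit on all rows at the selected penalty.
    """
    Xa = X.to_numpy(dtype=float)
    ya = y.loc[X.index].to_numpy(dtype=float)
    if not np.all(np.isfinite(ya)):
        raise ValueError("non-finite response")
    n = Xa.shape[0]
    if not 2 <= folds <= n:
        raise ValueError("need n >= folds >= 2")
    if lambdas is None:
        lmax = lambda_max(Xa, ya)
        if lmax == 0:
            lmax = 1e-8
        lambdas = np.geomspace(lmax, 1e-4 * lmax, 100)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty penalty grid")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xa))
    mse = np.zeros((lambdas.size, folds))
    descending = np.all(np.diff(lambdas) <= 0)
    for fi, (tr, te) in enumerate(splits):
        warm = None
        for li, lam in enumerate(lambdas):
            # the CV curve only ranks penalties; 1e-6 is ample there, the
            # final model below is refit at full precision
            warm = _fit_lasso(Xa[tr], ya[tr], lam,
                              warm=warm if descending else None, tol=1e-6)
            pred = Xa[te] @ warm.coef_ + warm.intercept_
            mse[li, fi] = float(np.mean((ya[te] - pred) ** 2))
    mean_mse = mse.mean(axis=1)
    best = int(np.argmin(mean_mse))
    final = _fit_lasso(Xa, ya, float(lambdas[best]))
    return RpvModel(
        features=list(X.columns),
        coefficients=final.coef_,
        intercept=float(final.intercept_),
        penalty=float(lambdas[best]),
        cv_folds=folds,
        cv_curve=pd.DataFrame({"lambda": lambdas, "mean_cv_mse": mean_mse}),
        metadata={"seed": seed, "n_train": n},
    )


def _fit_lasso(X, y, lam, warm=None, tol=None):
    # warm: reuse the previous (larger-lambda) solution along a descending
    # path; coordinate descent then needs few passes per grid point
    if warm is not None:
        warm.alpha = max(lam, 1e-12)
        model = warm
    elif lam == 0:
        model = Lasso(alpha=1e-12, fit_intercept=True, max_iter=100000,
                      tol=tol or 1e-12, warm_start=True)
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=50000,
                      tol=tol or 1e-10, warm_start=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def rpv_score(
    features: pd.DataFrame | pd.Series,
    model: RpvModel,
    factors: StandardizationFactors | None = None,
) -> pd.Series | float:
    """Apply the model: score = b + sum_j w_j * standardized feature_j.

    If ``factors`` is given, raw features are standardized with the
    training factors first; otherwise the input is assumed standardized.
    """
    single = isinstance(features, pd.Series)
    mat = features.to_frame().T if single else features
    if factors is not None:
        mat = apply_factors(mat, factors)
    missing = [f for f in model.features if f not in mat.columns]
    if missing:
        raise ValueError(f"missing model feature(s): {missing}")
    vals = mat[model.features].to_numpy(dtype=float)
    scores = model.intercept + vals @ model.coefficients
    if single:
        return float(scores[0])
    return pd.Series(scores, index=mat.index, name="rpv_score")


def aggregate_bilateral(mass_scores: pd.DataFrame) -> pd.Series:
    """Case score = max over the case's tumor masses.

    ``mass_scores`` needs columns case_id and rpv_score (one row per mass).
    """
    if mass_scores.empty:
        raise ValueError("no masses to aggregate")
    return mass_scores.groupby("case_id")["rpv_score"].max()


def rpv_survival_report(
    case_scores: pd.Series,
    clinical: pd.DataFrame,
    cut_quantile: float = 0.5,
    adjust_for: list[str] | None = None,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> dict:
    """Dichotomize the radiomic score and run the survival machinery.

    Returns KM curves per score group, the log-rank test, and a Cox fit of
    the high/low indicator (optionally adjusted for clinical covariates).
    """
    clin = clinical.loc[case_scores.index]
    labels = dichotomize_scores(case_scores, high_quantile=cut_quantile)
    chi2, p = logrank_test(clin[duration_col], clin[event_col], labels)
    covs = ["rpv_high"] + (adjust_for or [])
    fit = cox_fit(
        clin.assign(rpv_high=labels.to_numpy(dtype=float)),
        covs,
        duration_col=duration_col,
        event_col=event_col,
    )
    return {
        "labels": labels,
        "km": {
            int(g): km_estimate(
                clin.loc[labels == g, duration_col], clin.loc[labels == g, event_col]
            )
            for g in sorted(labels.unique())
        },
        "logrank_chi2": chi2,
        "logrank_p": p,
        "cox": fit,
    }
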