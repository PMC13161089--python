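"""Shared statistical layer.

Paired t-tests, covariate-adjusted multiple linear regression with
confidence intervals, z-scoring, and Holm step-down adjustment.  Every
higher-level analysis (entire-tract regressions, RSFC models, composite
construction) funnels through these routines so that estimates, standard
errors and p-values are computed in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelFit",
    "PairedTestResult",
    "paired_t",
    "fit_linear_model",
    "holm_adjust",
    "zscore",
    "ADJUSTMENT_SETS",
]

# Preset covariate-adjustment families.  Symptom-severity models adjust for
# demographics and injury recency; visuomotor models additionally adjust for
# video-game experience, a known predictor of decoupled-reach performance.
ADJUSTMENT_SETS = {
    "symptom": ["age", "sex", "sport_experience", "days_since_concussion"],
    "visuomotor": [
        "age",
        "sex",
        "sport_experience",
        "videogame_experience",
        "days_since_concussion",
    ],
}


@dataclass
class PairedTestResult:
    """Classical paired t-test on within-participant differences."""

    t: float
    df: int
    p: float
    mean_diff: float

    def summary(self) -> str:
        return (
            f"paired t({self.df}) = {self.t:.3f}, p = {self.p:.4g}, "
            f"mean difference = {self.mean_diff:.4g}"
        )


@dataclass
class ModelFit:
    """Ordinary least-squares fit with per-term inference.

    Attributes
    ----------
    terms : list of str
        Column names of the design, intercept first.
    params : ndarray
        Unstandardized coefficient estimates (B).
    bse : ndarray
        Standard errors.
    tvalues, pvalues : ndarray
        Per-term t statistics and two-sided p-values on t(df_resid).
    conf_int : ndarray, shape (p, 2)
        95% confidence intervals.
    rsquared : float
    df_resid : int
    nobs : int
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray
    rsquared: float
    df_resid: int
    nobs: int
    adjusted_pvalues: np.ndarray | None = field(default=None)

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        out = {
            "term": name,
            "B": float(self.params[i]),
            "SE": float(self.bse[i]),
            "t": float(self.tvalues[i]),
            "p": float(self.pvalues[i]),
            "ci_low": float(self.conf_int[i, 0]),
            "ci_high": float(self.conf_int[i, 1]),
        }
        if self.adjusted_pvalues is not None:
            out["p_adj"] = float(self.adjusted_pvalues[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "term": self.terms,
                "B": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
            }
        )
        if self.adjusted_pvalues is not None:
            df["p_adj"] = self.adjusted_pvalues
        df["R2"] = self.rsquared
        df["n"] = self.nobs
        return df

    def summary(self) -> str:
        return self.to_frame().to_string(index=False, float_format="%.6f")


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Paired t-test of ``x`` against ``y`` (difference x - y).

    Degenerate cases: all-zero differences give t = 0, p = 1; zero-variance
    differences with nonzero mean give an infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        return PairedTestResult(
            t=float(np.inf) * np.sign(mean), df=n - 1, p=0.0, mean_diff=mean
        )
    res = st.ttest_rel(x[ok], y[ok])
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean_diff=mean
    )


def _design_frame(
    data: pd.DataFrame, predictor: str, covariates: Sequence[str]
) -> pd.DataFrame:
    cols = [predictor, *covariates]
    X = data[cols].copy()
    # Sex (and any other two-level string column) becomes a 0/1 indicator.
    for c in X.columns:
        if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(X[c].dropna()))
            if len(levels) > 2:
                raise ValueError(f"categorical column {c!r} has >2 levels")
            X[c] = (X[c] == levels[-1]).astype(float)
    return X.astype(float)


def fit_linear_model(
    y: Sequence[float] | pd.Series,
    X: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
) -> ModelFit:
    """Covariate-adjusted ordinary least squares with per-term inference.

    Parameters
    ----------
    y : outcome vector, length n.
    X : design of predictors (no intercept column); a DataFrame keeps its
        column names as term names.
    add_intercept : prepend a constant column (default).

    Rows with any missing value are dropped (listwise deletion) and the
    retained count is reported in ``nobs``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != Xv.shape[0]:
        raise ValueError("y and X row counts differ")

    keep = np.isfinite(yv) & np.all(np.isfinite(Xv), axis=1)
    yv, Xv = yv[keep], Xv[keep]
    if add_intercept:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        names = ["intercept", *names]

    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"n = {n} observations for p = {p} parameters")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # name the offending columns for the caller
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    fit = sm.OLS(yv, Xv).fit()
    ci = np.asarray(fit.conf_int(alpha=0.05))
    return ModelFit(
        terms=names,
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        conf_int=ci,
        rsquared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
        nobs=n,
    )


def fit_adjusted_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    profile: str = "symptom",
    covariates: Sequence[str] | None = None,
) -> ModelFit:
    """Fit ``outcome ~ predictor + covariates`` from a tidy table.

    ``profile`` selects a preset adjustment family from
    :data:`ADJUSTMENT_SETS`; an explicit ``covariates`` list overrides it.
    """
    covs = list(covariates) if covariates is not None else ADJUSTMENT_SETS[profile]
    covs = [c for c in covs if c in data.columns]
    X = _design_frame(data, predictor, covs)
    return fit_linear_model(data[outcome], X)


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down familywise adjustment, order-preserving.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def zscore(
    v: Sequence[float], reference: tuple[float, float] | None = None
) -> np.ndarray:
    """Standardize ``v`` against (mean, sd), or against itself.

    Self-referenced standardization uses the sample SD (ddof=1), matching
    the convention for cohort z-scores.
    """
    v = np.asarray(v, dtype=float)
    if reference is None:
        mean, sd = float(np.nanmean(v)), float(np.nanstd(v, ddof=1))
    else:
        mean, sd = reference
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("zero or invalid standard deviation")
    return (v - mean) / sd
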