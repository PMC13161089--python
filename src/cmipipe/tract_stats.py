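"""Along-tract and entire-tract statistics for white-matter profiles.

A tract profile is a 1D curve per participant: a diffusion measure (FA or
MD) averaged at L consecutive cross-sections along a named tract.  Two
analyses are provided:

* :class:`AlongTractGLM` — an ordinary least-squares model fitted
  independently at every cross-section, with familywise control by
  cluster-based permutation: contiguous supra-threshold runs of the
  contrast t-statistic are measured by their size and compared against
  the permutation distribution of the maximal null cluster size
  (Freedman–Lane residual permutation, so nuisance covariates are
  respected).  Bonferroni doubling is applied across hemispheres for
  bilateral tracts.
* :func:`entire_tract_regression` — a single covariate-adjusted linear
  model of an outcome on the tract-mean value, with Holm step-down
  adjustment across the terms of each regression.

The model/results split follows the usual pattern: construct an
:class:`AlongTractGLM` from data, call :meth:`~AlongTractGLM.fit`, and
read estimates, clusters and the summary table off the returned
:class:`AlongTractResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .inference import ModelFit, fit_linear_model, holm_adjust

__all__ = [
    "TractProfile",
    "ClusterResult",
    "AlongTractGLM",
    "AlongTractResults",
    "pointwise_glm",
    "form_clusters",
    "entire_tract_regression",
    "EntireTractModel",
]

HEMISPHERES = {"left", "right", "commissural"}


@dataclass
class TractProfile:
    """A measure sampled at L cross-sections along one tract.

    ``values`` is participants x L; every participant is sampled at the
    same cross-sections.  ``point_spacing_mm`` converts cluster extents
    from points to millimetres along the tract.
    """

    tract: str
    hemisphere: str
    measure: str
    values: np.ndarray
    point_spacing_mm: float = 1.0
    participants: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {sorted(HEMISPHERES)}")
        if self.values.shape[1] < 2:
            raise ValueError("profile needs at least 2 cross-sections")
        if self.point_spacing_mm <= 0:
            raise ValueError("point spacing must be positive")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def mean_values(self) -> np.ndarray:
        """Entire-tract mean per participant."""
        return self.values.mean(axis=1)


@dataclass
class ClusterResult:
    """A contiguous supra-threshold run along a profile."""

    tract: str
    hemisphere: str
    measure: str
    start: int
    end: int  # inclusive
    size_points: int
    size_mm: float
    peak_t: float
    sign: int
    cluster_p: float | None = None
    bonferroni_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "tract": self.tract,
            "hemisphere": self.hemisphere,
            "measure": self.measure,
            "start": self.start,
            "end": self.end,
            "size_points": self.size_points,
            "size_mm": self.size_mm,
            "peak_t": self.peak_t,
            "sign": self.sign,
            "cluster_p": self.cluster_p,
            "bonferroni_p": self.bonferroni_p,
        }


def _prepare_design(
    X: pd.DataFrame | np.ndarray,
    contrast: str | int,
    add_intercept: bool,
) -> tuple[np.ndarray, list[str], int]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if add_intercept:
        Xv = np.column_stack([np.ones(Xv.shape[0]), Xv])
        names = ["intercept", *names]
    if isinstance(contrast, str):
        c_idx = names.index(contrast)
    else:
        c_idx = int(contrast) + (1 if add_intercept else 0)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        bad = [
            names[j]
            for j in range(Xv.shape[1])
            if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return Xv, names, c_idx


def pointwise_glm(
    values: np.ndarray,
    X: np.ndarray,
    contrast_index: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS at every cross-section; t and two-sided p for one contrast.

    ``values`` is n x L, ``X`` the full n x p design (intercept included).
    Returns (beta, t, p), each of length L, with beta the contrast
    coefficient and p from t(n - p).
    """
    Y = np.asarray(values, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} rows for p = {p} design columns")
    pinvX = np.linalg.pinv(X)
    B = pinvX @ Y  # p x L
    resid = Y - X @ B
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    sigma2[sigma2 < _VAR_FLOOR] = 0.0  # exact fits, not real variance
    xtx_inv_cc = float((pinvX @ pinvX.T)[contrast_index, contrast_index])
    se = np.sqrt(sigma2 * xtx_inv_cc)
    beta = B[contrast_index]
    t = _safe_t(beta, se)
    pvals = 2.0 * st.t.sf(np.abs(t), df)
    return beta, t, pvals


_VAR_FLOOR = 1e-25  # below this, residual variance is rounding, not noise


def _safe_t(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    # an exact (zero-residual) nonzero effect has an infinite t; an exact
    # zero effect with zero residual variance has t = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            se > 0,
            np.divide(beta, se, out=np.zeros_like(beta), where=se > 0),
            np.where(np.abs(beta) > 1e-12, np.sign(beta) * np.inf, 0.0),
        )


def form_clusters(
    t: np.ndarray,
    threshold: float,
    *,
    tract: str = "",
    hemisphere: str = "commissural",
    measure: str = "",
    point_spacing_mm: float = 1.0,
) -> list[ClusterResult]:
    """Maximal contiguous runs with |t| above threshold.

    Positive and negative excursions form separate clusters: a run that
    crosses zero is split at the sign change, so effects of opposite
    direction are reported separately.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    t = np.asarray(t, dtype=float)
    supra = np.abs(t) > threshold
    clusters: list[ClusterResult] = []
    i = 0
    L = t.size
    while i < L:
        if not supra[i]:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        while j + 1 < L and supra[j + 1] and (t[j + 1] > 0) == (sign > 0):
            j += 1
        seg = t[i : j + 1]
        clusters.append(
            ClusterResult(
                tract=tract,
                hemisphere=hemisphere,
                measure=measure,
                start=i,
                end=j,
                size_points=j - i + 1,
                size_mm=(j - i + 1) * point_spacing_mm,
                peak_t=float(seg[np.argmax(np.abs(seg))]),
                sign=sign,
            )
        )
        i = j + 1
    return clusters


def _max_cluster_sizes(t_mat: np.ndarray, threshold: float) -> np.ndarray:
    """Largest supra-threshold run length per row of ``t_mat`` (two-sided).

    Sign changes split runs, mirroring :func:`form_clusters`.  Vectorised
    over rows for the permutation loop.
    """
    supra = np.abs(t_mat) > threshold
    signed = np.where(supra, np.sign(t_mat), 0.0).astype(np.int8)
    K, L = signed.shape
    best = np.zeros(K, dtype=np.int64)
    run = np.zeros(K, dtype=np.int64)
    prev = np.zeros(K, dtype=np.int8)
    for j in range(L):
        col = signed[:, j]
        cont = (col != 0) & (col == prev)
        run = np.where(cont, run + 1, np.where(col != 0, 1, 0))
        best = np.maximum(best, run)
        prev = col
    return best


class AlongTractGLM:
    """Pointwise linear model along a tract profile.

    Parameters
    ----------
    profile : TractProfile
        Participants x cross-sections values.
    design : DataFrame or ndarray
        Predictor columns (covariate of interest plus nuisance
        covariates); an intercept is prepended unless ``add_intercept``
        is False.
    contrast : str or int
        Which design column is the covariate of interest.
    """

    def __init__(
        self,
        profile: TractProfile,
        design: pd.DataFrame | np.ndarray,
        contrast: str | int = 0,
        add_intercept: bool = True,
    ) -> None:
        self.profile = profile
        self.X, self.term_names, self.contrast_index = _prepare_design(
            design, contrast, add_intercept
        )
        if self.X.shape[0] != profile.n_participants:
            raise ValueError("design rows must match profile participants")
        n, p = self.X.shape
        if n <= p:
            raise ValueError(f"n = {n} participants for p = {p} parameters")
        self.df_resid = n - p

    @classmethod
    def from_dataframe(
        cls,
        profile: TractProfile,
        data: pd.DataFrame,
        predictor: str,
        covariates: Sequence[str] = (),
    ) -> "AlongTractGLM":
        cols = [predictor, *covariates]
        X = data[cols].copy()
        for c in X.columns:
            if X[c].dtype == object:
                levels = sorted(pd.unique(X[c].dropna()))
                X[c] = (X[c] == levels[-1]).astype(float)
        return cls(profile, X.astype(float), contrast=predictor)

    def threshold_t(self, alpha: float = 0.05) -> float:
        """Two-sided cluster-forming threshold on the |t| scale."""
        return float(st.t.ppf(1.0 - alpha / 2.0, self.df_resid))

    def fit(
        self,
        n_perm: int = 5000,
        alpha: float = 0.05,
        seed: int | None = None,
        cluster_stat: str = "size",
        batch: int = 500,
    ) -> "AlongTractResults":
        """Fit the pointwise GLM and run the cluster permutation test.

        The permutation scheme is Freedman-Lane: the outcome profiles are
        residualised on the nuisance design (everything except the
        contrast column), residual rows are permuted, the reduced-model
        fit is added back, and the full model is refitted.  The null
        statistic is the maximal cluster size over the profile, pooled
        over both signs.  cluster_p = (1 + #{null >= observed}) /
        (1 + n_perm), so the smallest attainable p is 1/(1 + n_perm).
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if cluster_stat not in ("size", "mass"):
            raise ValueError("cluster_stat must be 'size' or 'mass'")
        Y = self.profile.values
        n = Y.shape[0]
        if n < 7:
            import warnings

            warnings.warn(
                f"n = {n} participants gives a coarse permutation distribution",
                stacklevel=2,
            )
        X = self.X
        c = self.contrast_index
        beta, tvals, pvals = pointwise_glm(Y, X, c)
        tstar = self.threshold_t(alpha)
        hemi_factor = 2 if self.profile.hemisphere in ("left", "right") else 1
        clusters = form_clusters(
            tvals,
            tstar,
            tract=self.profile.tract,
            hemisphere=self.profile.hemisphere,
            measure=self.profile.measure,
            point_spacing_mm=self.profile.point_spacing_mm,
        )

        # Freedman-Lane null distribution of the maximal cluster size.
        Z = np.delete(X, c, axis=1)
        pinvZ = np.linalg.pinv(Z)
        fitted_reduced = Z @ (pinvZ @ Y)
        E = Y - fitted_reduced
        rng = np.random.default_rng(seed)
        pinvX = np.linalg.pinv(X)
        xtx_inv_cc = float((pinvX @ pinvX.T)[c, c])
        df = self.df_resid
        null_max = np.empty(n_perm, dtype=float)
        done = 0
        while done < n_perm:
            k = min(batch, n_perm - done)
            idx = np.argsort(rng.random((k, n)), axis=1)  # k independent perms
            Ystar = fitted_reduced[None, :, :] + E[idx]  # k x n x L
            B = np.einsum("pn,knl->kpl", pinvX, Ystar)
            resid = Ystar - np.einsum("np,kpl->knl", X, B)
            sigma2 = np.einsum("knl,knl->kl", resid, resid) / df
            sigma2[sigma2 < _VAR_FLOOR] = 0.0
            se = np.sqrt(sigma2 * xtx_inv_cc)
            tperm = _safe_t(B[:, c, :], se)
            if cluster_stat == "size":
                null_max[done : done + k] = _max_cluster_sizes(tperm, tstar)
            else:
                null_max[done : done + k] = _max_cluster_mass(tperm, tstar)
            done += k

        for cl in clusters:
            obs = (
                cl.size_points
                if cluster_stat == "size"
                else float(np.sum(np.abs(tvals[cl.start : cl.end + 1]) - tstar))
            )
            cl.cluster_p = float((1 + np.sum(null_max >= obs)) / (1 + n_perm))
            cl.bonferroni_p = float(min(1.0, cl.cluster_p * hemi_factor))

        return AlongTractResults(
            model=self,
            beta=beta,
            tvalues=tvals,
            pvalues=pvals,
            threshold=tstar,
            alpha=alpha,
            n_perm=n_perm,
            clusters=clusters,
            null_max=null_max,
            hemisphere_factor=hemi_factor,
        )


def _max_cluster_mass(t_mat: np.ndarray, threshold: float) -> np.ndarray:
    """Largest summed supra-threshold exceedance per row (optional statistic)."""
    out = np.empty(t_mat.shape[0])
    for r in range(t_mat.shape[0]):
        cls = form_clusters(t_mat[r], threshold)
        out[r] = max(
            (float(np.sum(np.abs(t_mat[r, c.start : c.end + 1]) - threshold)) for c in cls),
            default=0.0,
        )
    return out


@dataclass
class AlongTractResults:
    """Results of a fitted :class:`AlongTractGLM`."""

    model: AlongTractGLM
    beta: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    clusters: list[ClusterResult]
    null_max: np.ndarray
    hemisphere_factor: int

    def significant_clusters(self, alpha: float | None = None) -> list[ClusterResult]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.bonferroni_p is not None and c.bonferroni_p <= a]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.clusters])

    def summary(self) -> str:
        p = self.model.profile
        head = (
            f"Along-tract GLM: {p.measure} along {p.tract} ({p.hemisphere}), "
            f"n = {p.n_participants}, L = {p.n_points}, "
            f"contrast = {self.model.term_names[self.model.contrast_index]}\n"
            f"cluster-forming |t| > {self.threshold:.3f} "
            f"(p = {self.alpha:.3g} two-sided, df = {self.model.df_resid}); "
            f"{self.n_perm} permutations; hemisphere Bonferroni x{self.hemisphere_factor}\n"
        )
        if not self.clusters:
            return head + "No supra-threshold clusters."
        return head + self.to_frame().to_string(index=False, float_format="%.4f")

    def plot(self, ax=None):
        """t-statistic profile with the threshold and clusters marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.tvalues.size) * self.model.profile.point_spacing_mm
        ax.plot(x, self.tvalues, color="k", lw=1.2)
        ax.axhline(self.threshold, color="r", ls="--", lw=0.8)
        ax.axhline(-self.threshold, color="r", ls="--", lw=0.8)
        for c in self.clusters:
            ax.axvspan(
                c.start * self.model.profile.point_spacing_mm,
                c.end * self.model.profile.point_spacing_mm,
                alpha=0.2,
                color="C0" if (c.bonferroni_p or 1) > self.alpha else "C1",
            )
        ax.set_xlabel("position along tract (mm)")
        ax.set_ylabel("t")
        ax.set_title(f"{self.model.profile.tract} ({self.model.profile.measure})")
        return ax


@dataclass
class EntireTractModel:
    """Covariate-adjusted regression of an outcome on a tract-mean value."""

    tract: str
    hemisphere: str
    measure: str
    outcome: str
    fit: ModelFit

    def to_frame(self) -> pd.DataFrame:
        df = self.fit.to_frame()
        df.insert(0, "outcome", self.outcome)
        df.insert(0, "measure", self.measure)
        df.insert(0, "hemisphere", self.hemisphere)
        df.insert(0, "tract", self.tract)
        return df


def entire_tract_regression(
    profile: TractProfile,
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    mean_values: np.ndarray | None = None,
) -> EntireTractModel:
    """Regress ``outcome`` on the entire-tract mean, adjusting for covariates.

    The tract mean (FA or MD averaged over all cross-sections) enters as
    the predictor of interest.  Holm step-down adjustment is applied
    across all non-intercept terms of the regression — the family is the
    single regression analysis.
    """
    mv = profile.mean_values() if mean_values is None else np.asarray(mean_values)
    X = pd.DataFrame({"tract_mean": mv}, index=data.index)
    for c in covariates:
        col = data[c]
        if col.dtype == object:
            levels = sorted(pd.unique(col.dropna()))
            col = (col == levels[-1]).astype(float)
        X[c] = col.astype(float)
    fit = fit_linear_model(data[outcome], X)
    adj = np.full(len(fit.terms), np.nan)
    non_int = [i for i, t in enumerate(fit.terms) if t != "intercept"]
    adj_vals = holm_adjust(fit.pvalues[non_int])
    for i, v in zip(non_int, adj_vals):
        adj[i] = v
    fit.adjusted_pvalues = adj
    return EntireTractModel(
        tract=profile.tract,
        hemisphere=profile.hemisphere,
        measure=profile.measure,
        outcome=outcome,
        fit=fit,
    )
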