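"""Morphospace structure and phylogenetically informed regression.

Covers the species-level questions: do species form clusters in trait /
shape space (k-means with an elbow rule on the within-group sum of
squares); do those clusters track habitat variables or relatedness (MANOVA
/ ANOVA with Tukey HSD contrasts); and how much morphological variation do
habitat features and Brownian-motion relatedness explain, separately and
together (GLS regression with likelihood-ratio model comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .tree import BMCovariance

__all__ = [
    "ClusterResult",
    "LRTResult",
    "screen_collinear",
    "kmeans_morphospace",
    "cluster_association",
    "PGLS",
    "PGLSResults",
    "pgls_fit",
    "lrt_compare",
    "sex_difference",
]


@dataclass
class ClusterResult:
    assignment: pd.Series  # species -> cluster id (1-based, contiguous)
    wss: dict  # k -> within-group sum of squares
    chosen_k: int
    k_range: list = field(default_factory=list)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Habitat-variable screening
# ---------------------------------------------------------------------------

def screen_collinear(habitat: pd.DataFrame, r_max: float = 0.75) -> list[str]:
    """Greedy collinearity filter in column order.

    A variable is retained iff its absolute Pearson correlation with every
    already-retained variable is below ``r_max``.  Constant columns are
    excluded with a warning (their correlation is undefined).
    """
    num = habitat.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need >= 2 numeric variables to screen")
    kept: list[str] = []
    for col in num.columns:
        x = num[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant variable {col!r} excluded")
            continue
        ok = True
        for kcol in kept:
            r = np.corrcoef(x, num[kcol].to_numpy(dtype=float))[0, 1]
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            kept.append(col)
    return kept


# ---------------------------------------------------------------------------
# k-means morphospace
# ---------------------------------------------------------------------------

def kmeans_morphospace(
    X, k_range=range(1, 11), n_init: int = 10, seed: int = 0
) -> ClusterResult:
    """Best-of-``n_init`` k-means over ``k_range``; k chosen by the elbow
    rule (maximum second difference of the within-group sum of squares)."""
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        labels = list(range(len(Xa)))
    ks = sorted(k_range)
    n = len(Xa)
    if ks[-1] > n:
        raise ValueError(f"k = {ks[-1]} exceeds n = {n}")
    wss: dict[int, float] = {}
    assigns: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xa)
        wss[k] = float(km.inertia_)
        assigns[k] = km.labels_
    if len(ks) >= 3:
        w = np.array([wss[k] for k in ks])
        second = w[:-2] - 2.0 * w[1:-1] + w[2:]
        chosen = ks[1 + int(np.argmax(second))]
    else:
        chosen = ks[int(np.argmin([wss[k] for k in ks]))]
    # contiguous 1-based ids in order of first appearance
    raw = assigns[chosen]
    order: dict[int, int] = {}
    mapped = np.array([order.setdefault(c, len(order) + 1) for c in raw])
    return ClusterResult(
        assignment=pd.Series(mapped, index=labels, name="cluster"),
        wss=wss,
        chosen_k=chosen,
        k_range=ks,
    )


# ---------------------------------------------------------------------------
# Cluster association: MANOVA / ANOVA + Tukey
# ---------------------------------------------------------------------------

def _wilks_manova(Y: np.ndarray, groups: np.ndarray) -> dict:
    """One-way MANOVA: Wilks' Lambda with Rao's F approximation; falls back
    to Pillai's trace if the within-group SSCP is singular."""
    levels = np.unique(groups)
    g, (N, p) = len(levels), Y.shape
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lv in levels:
        sub = Y[groups == lv]
        m = sub.mean(axis=0)
        d = sub - m
        W += d.T @ d
        B += len(sub) * np.outer(m - grand, m - grand)
    q = g - 1
    sign, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign <= 0 or not np.isfinite(logdet_w):
        warnings.warn("singular within-group SSCP; using Pillai's trace")
        V = float(np.trace(B @ np.linalg.pinv(B + W)))
        s = min(p, q)
        m_ = (abs(p - q) - 1) / 2.0
        n_ = (N - g - p - 1) / 2.0
        df1 = s * (2 * m_ + s + 1)
        df2 = s * (2 * n_ + s + 1)
        F = (df2 / df1) * V / (s - V) if s > V else np.inf
        return {"method": "pillai", "statistic": V, "F": F, "df1": df1,
                "df2": df2, "p": float(stats.f.sf(F, df1, df2))}
    lam = float(np.exp(logdet_w - logdet_t))
    if p**2 + q**2 - 5 > 0:
        t = np.sqrt((p**2 * q**2 - 4.0) / (p**2 + q**2 - 5.0))
    else:
        t = 1.0
    df1 = p * q
    df2 = ((N - g) - (p - q + 1) / 2.0) * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return {"method": "wilks", "statistic": lam, "F": float(F), "df1": df1,
            "df2": float(df2), "p": float(stats.f.sf(F, df1, df2))}


def _relatedness_coords(R: BMCovariance, var_frac: float = 0.95) -> np.ndarray:
    """Leading principal coordinates of the relatedness matrix (enough axes
    for ``var_frac`` of the variance) -- species as points."""
    M = np.asarray(R.R, dtype=float)
    Mc = M - M.mean(0, keepdims=True) - M.mean(1, keepdims=True) + M.mean()
    w, V = np.linalg.eigh(Mc)
    idx = np.argsort(w)[::-1]
    w, V = np.clip(w[idx], 0, None), V[:, idx]
    frac = np.cumsum(w) / w.sum()
    keep = int(np.searchsorted(frac, var_frac - 1e-12)) + 1
    return V[:, :keep] * np.sqrt(w[:keep])


def cluster_association(assignment: pd.Series, predictors, tukey: bool = True) -> dict:
    """Test whether k-means clusters track a predictor set.

    ``predictors`` is a species x variables DataFrame/array (habitat
    features) or a :class:`BMCovariance` (relatedness; species become their
    leading principal coordinates).  Returns the MANOVA table plus (when
    ``tukey``) Tukey HSD pairwise contrasts per variable.
    """
    groups = np.asarray(assignment)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 clusters")
    if isinstance(predictors, BMCovariance):
        Y = _relatedness_coords(predictors)
        names = [f"pco{i + 1}" for i in range(Y.shape[1])]
    elif isinstance(predictors, pd.DataFrame):
        num = predictors.select_dtypes(include=[np.number])
        Y = num.to_numpy(dtype=float)
        names = list(num.columns)
    else:
        Y = np.atleast_2d(np.asarray(predictors, dtype=float))
        if Y.shape[0] != len(groups):
            Y = Y.T
        names = [f"v{i + 1}" for i in range(Y.shape[1])]
    res = _wilks_manova(Y, groups)
    tables: dict = {}
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for j, nm in enumerate(names):
            if np.std(Y[:, j]) == 0:
                continue
            t = pairwise_tukeyhsd(Y[:, j], groups)
            tables[nm] = pd.DataFrame(
                t.summary().data[1:], columns=t.summary().data[0]
            )
    res["tukey"] = tables
    res["variables"] = names
    return res


def sex_difference(specimens: pd.DataFrame, trait: str) -> dict:
    """Two-sample t-test of a trait between sexes (specimen-level)."""
    m = specimens.loc[specimens["sex"] == "M", trait].to_numpy(dtype=float)
    f = specimens.loc[specimens["sex"] == "F", trait].to_numpy(dtype=float)
    t, p = stats.ttest_ind(m, f)
    return {"trait": trait, "t": float(t), "df": len(m) + len(f) - 2, "p": float(p)}


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

class PGLS:
    """Generalized least squares with a phylogenetic error correlation.

    ``y`` may be a vector or a species x features matrix (each feature is
    fitted with the shared design and correlation; log-likelihoods are
    summed).  ``corr=None`` gives ordinary least squares.  Maximum
    likelihood: ``sigma2_hat = r' R^-1 r / n`` per feature.
    """

    def __init__(self, y, X=None, corr=None, add_intercept: bool = True):
        if isinstance(y, pd.DataFrame):
            self.endog_names = list(y.columns)
            y = y.to_numpy(dtype=float)
        elif isinstance(y, pd.Series):
            self.endog_names = [y.name or "y"]
            y = y.to_numpy(dtype=float)[:, None]
        else:
            y = np.asarray(y, dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            self.endog_names = [f"y{i}" for i in range(y.shape[1])]
        n = y.shape[0]
        if X is None:
            Xd = np.ones((n, 1))
            names = ["const"]
        elif isinstance(X, pd.DataFrame):
            Xd = X.to_numpy(dtype=float)
            names = list(X.columns)
            if add_intercept:
                Xd = np.column_stack([np.ones(n), Xd])
                names = ["const"] + names
        else:
            Xd = np.asarray(X, dtype=float)
            if Xd.ndim == 1:
                Xd = Xd[:, None]
            names = [f"x{i}" for i in range(Xd.shape[1])]
            if add_intercept:
                Xd = np.column_stack([np.ones(n), Xd])
                names = ["const"] + names
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            # identify aliased columns by incremental rank
            aliased, r = [], 0
            for j in range(Xd.shape[1]):
                rj = np.linalg.matrix_rank(Xd[:, : j + 1])
                if rj == r:
                    aliased.append(names[j])
                r = rj
            raise ValueError(f"singular design; aliased columns: {aliased}")
        if corr is None:
            R = None
        else:
            R = corr.R if isinstance(corr, BMCovariance) else np.asarray(corr, dtype=float)
        self.y, self.X, self.R = y, Xd, R
        self.exog_names = names
        self.has_corr = R is not None

    def fit(self) -> "PGLSResults":
        y, Xd = self.y, self.X
        n, m = y.shape
        p = Xd.shape[1]
        if self.R is None:
            Lw = None
            yw, Xw = y, Xd
            logdet_R = 0.0
        else:
            from scipy.linalg import solve_triangular

            R = self.R + 1e-8 * np.eye(n)
            Lw = np.linalg.cholesky(R)
            yw = solve_triangular(Lw, y, lower=True)
            Xw = solve_triangular(Lw, Xd, lower=True)
            logdet_R = 2.0 * float(np.sum(np.log(np.diag(Lw))))
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid_w = yw - Xw @ beta
        rss = np.sum(resid_w**2, axis=0)
        sigma2 = rss / n
        loglik = float(
            np.sum(
                -0.5 * n * np.log(2.0 * np.pi)
                - 0.5 * n * np.log(np.where(sigma2 > 0, sigma2, 1e-300))
                - 0.5 * logdet_R
                - 0.5 * n
            )
        )
        # adjusted R^2 in the whitened space, averaged across features
        ym = yw - yw.mean(axis=0)
        tss = np.sum(ym**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - rss / np.where(tss > 0, tss, np.nan)
        adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - p, 1)
        # coefficients + one variance per feature, plus one parameter per
        # feature for the phylogenetic correlation when present (the BM
        # relatedness structure is an estimated model component for LRT
        # bookkeeping, like a Pagel-lambda switch)
        n_params = m * (p + 1) + (m if self.R is not None else 0)
        return PGLSResults(self, beta, sigma2, loglik, n_params,
                           float(np.nanmean(adj)))


class PGLSResults:
    def __init__(self, model, params, sigma2, loglik, n_params, adj_r2):
        self.model = model
        self.params = params  # (p, m)
        self.sigma2 = sigma2
        self.loglik = loglik
        self.n_params = n_params
        self.adj_r2 = adj_r2
        self.exog_names = model.exog_names

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.X @ self.params

    def summary(self) -> str:
        lines = [
            "GLS regression"
            + (" (phylogenetic correlation)" if self.model.has_corr else " (OLS)"),
            f"  n = {len(self.model.y)}   features = {self.model.y.shape[1]}   "
            f"params = {self.n_params}",
            f"  loglik = {self.loglik:.4f}   adj R2 = {self.adj_r2:.4f}",
        ]
        for i, nm in enumerate(self.exog_names):
            vals = ", ".join(format(v, ".4g") for v in np.atleast_1d(self.params[i]))
            lines.append(f"  {nm:>16s}: {vals}")
        return "\n".join(lines)

    def lr_test(self, reduced: "PGLSResults") -> LRTResult:
        return lrt_compare(self, reduced)


def pgls_fit(y, Xp=None, R=None, add_intercept: bool = True) -> PGLSResults:
    """Operation-level wrapper: GLS fit of ``y`` on ``Xp`` with correlation
    ``R`` (identity / OLS when absent)."""
    return PGLS(y, Xp, corr=R, add_intercept=add_intercept).fit()


def lrt_compare(full: PGLSResults, reduced: PGLSResults) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*dLL ~ chi2(d params)."""
    full_names = set(full.exog_names)
    red_names = set(reduced.exog_names)
    if not red_names <= full_names:
        raise ValueError("models are not nested (predictor sets differ)")
    df = full.n_params - reduced.n_params
    if df < 1:
        if red_names == full_names and full.n_params == reduced.n_params:
            return LRTResult(statistic=0.0, df=1, p=1.0)
        raise ValueError("full model must have more parameters than reduced")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))
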