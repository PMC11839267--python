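"""Phylogenetic ridge regression: branch-wise evolutionary rates and shifts.

Tip trait values are regressed on the matrix of root-to-tip branch-length
paths; each coefficient is the rate of change along one branch, and partial
sums along root-to-node paths give ancestral state estimates.  An L2 penalty
(chosen by generalized cross-validation) regularizes the under-determined
system.  Rate *shifts* are then located by comparing mean absolute rates
inside a clade (or a habitat state) against the background, with
randomization p-values and Bonferroni control.

The solver exploits the push-through identity: with ``M = L L^T`` (tips x
tips), the root-unpenalized ridge solution is

    root = 1' (M + lam I)^-1 y / 1' (M + lam I)^-1 1
    beta = L' (M + lam I)^-1 (y - root 1)

which remains well-defined at ``lam = 0`` (the minimum-norm interpolant,
the limit of the ridge path), so only an n x n eigendecomposition is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "PathMatrix",
    "RateShiftResult",
    "PhylogeneticRidge",
    "RidgeRatesResults",
    "build_path_matrix",
    "fit_ridge",
    "select_lambda",
    "search_shift_clade",
    "search_shift_state",
]


@dataclass
class PathMatrix:
    """Tips x branches design: ``L[i, b]`` = length of branch b if b lies on
    the root-to-tip path of tip i, else 0.  One branch per non-root node;
    row sums equal root-to-tip depths.  The root state enters as an
    unpenalized intercept, not a column."""

    taxa: list[str]
    branches: list[int]  # node ids (one per non-root node), preorder
    L: np.ndarray

    @property
    def brlen(self) -> np.ndarray:
        return self.L.max(axis=0)


@dataclass
class RateShiftResult:
    unit: object  # clade node id or state label
    rate_delta: float  # mean |rate| inside - mean |rate| background
    p_raw: float
    p_adjusted: float
    direction: str  # "slower" | "faster"
    n_branches: int


def build_path_matrix(tree: PhyloTree) -> PathMatrix:
    branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    tips = tree.tip_ids
    pos = {t: k for k, t in enumerate(tips)}
    L = np.zeros((len(tips), len(branches)))
    desc = tree.tip_descendants()
    for col, v in enumerate(branches):
        idx = [pos[t] for t in desc[v]]
        L[idx, col] = tree.brlen[v]
    return PathMatrix(taxa=tree.taxa, branches=branches, L=L)


class PhylogeneticRidge:
    """Model: species trait values explained by per-branch rates of change.

    Parameters
    ----------
    tree : PhyloTree
    X : DataFrame (species x traits), 1-D Series, or array; rows must be
        indexable by the tree's taxa (DataFrames are reordered by index).
    """

    def __init__(self, tree: PhyloTree, X, taxa=None):
        self.tree = tree
        self.path = build_path_matrix(tree)
        if isinstance(X, pd.DataFrame):
            X = X.loc[self.path.taxa]
            self.trait_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        elif isinstance(X, pd.Series):
            X = X.loc[self.path.taxa].to_numpy(dtype=float)[:, None]
            self.trait_names = ["trait"]
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if taxa is not None and list(taxa) != self.path.taxa:
                order = [list(taxa).index(t) for t in self.path.taxa]
                X = X[order]
            self.trait_names = [f"trait{i}" for i in range(X.shape[1])]
        if X.shape[0] != len(self.path.taxa):
            raise ValueError("trait matrix rows do not match tree tips")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite trait values")
        self.X = X
        M = self.path.L @ self.path.L.T
        self._mu, self._Q = np.linalg.eigh(M)
        self._mu = np.clip(self._mu, 0.0, None)
        # BM tip covariance (unit rate), for the per-branch null sd of rates
        from .tree import bm_covariance

        self._C = bm_covariance(tree).C

    def _rate_null_sd(self, lam: float) -> np.ndarray:
        """Per-branch sd of the rate estimator under unit-rate BM.

        beta = A y with A = L'(M + lam I)^-1 (I - 1 w'); under BM
        cov(y) = sigma^2 C, so sd_b = sigma * sqrt(diag(A C A')).  Branches
        differ strongly in this sd (terminal vs. deep), so raw |rates| are
        not exchangeable; the shift searches permute standardized rates.
        """
        Q, mu = self._Q, self._mu
        d = mu + lam
        floor = 1e-12 * max(mu.max(), 1.0)
        d = np.where(d < floor, floor, d)
        Minv = (Q / d) @ Q.T
        one = np.ones(len(d))
        w = Minv @ one / float(one @ Minv @ one)
        A = self.path.L.T @ Minv @ (np.eye(len(d)) - np.outer(one, w))
        var = np.einsum("bi,ij,bj->b", A, self._C, A)
        sd = np.sqrt(np.clip(var, 0.0, None))
        sd[sd < 1e-12] = np.nan  # zero-length/uninformative branches
        return sd

    # -- solving ---------------------------------------------------------
    def _solve(self, y: np.ndarray, lam: float):
        """Return (root, beta, rss, df) for one trait vector."""
        Q, mu = self._Q, self._mu
        d = mu + lam
        if lam == 0.0:
            d = np.where(d < 1e-12 * max(mu.max(), 1.0), 1e-12 * max(mu.max(), 1.0), d)
        Qty = Q.T @ y
        Qt1 = Q.T @ np.ones(len(y))
        winv_y = Q @ (Qty / d)
        winv_1 = Q @ (Qt1 / d)
        root = float(np.ones(len(y)) @ winv_y) / float(np.ones(len(y)) @ winv_1)
        resid_core = Q @ ((Qty - root * Qt1) / d)
        beta = self.path.L.T @ resid_core
        resid = lam * resid_core  # y - fitted
        rss = float(resid @ resid)
        df = float(np.sum(mu / d)) + 1.0
        return root, beta, rss, df

    def select_lambda(self, y: np.ndarray, n_grid: int = 30) -> float:
        """GCV over a 30-point log grid scaled by tr(LL')/n."""
        n = len(y)
        if n < 4:
            raise ValueError("need >= 4 tips for GCV")
        scale = float(self._mu.sum()) / n
        grid = scale * np.logspace(-6, 3, n_grid)
        if np.var(y) == 0:
            warnings.warn("zero-variance response; returning grid maximum")
            return float(grid[-1])
        best, best_lam = np.inf, float(grid[-1])
        for lam in grid:
            _, _, rss, df = self._solve(y, float(lam))
            denom = max(n - df, 1e-8)
            gcv = n * rss / denom**2
            if gcv < best:
                best, best_lam = gcv, float(lam)
        return best_lam

    def fit(self, lam: float | None = None) -> "RidgeRatesResults":
        """Fit per trait; ``lam=None`` selects the penalty by GCV per trait."""
        if lam is not None and lam < 0:
            raise ValueError("lambda must be >= 0")
        n, k = self.X.shape
        lams = np.empty(k)
        roots = np.empty(k)
        betas = np.empty((self.path.L.shape[1], k))
        rss = np.empty(k)
        for j in range(k):
            lj = self.select_lambda(self.X[:, j]) if lam is None else float(lam)
            r, b, s, _ = self._solve(self.X[:, j], lj)
            lams[j], roots[j], betas[:, j], rss[j] = lj, r, b, s
        return RidgeRatesResults(self, lams, roots, betas, rss)


class RidgeRatesResults:
    """Per-branch rate estimates, ancestral states, and shift searches."""

    def __init__(self, model, lams, roots, betas, rss):
        self.model = model
        self.tree = model.tree
        self.lambdas = lams
        self.root_estimate = roots
        self.coefs = betas  # branches x traits (signed, trait units / time)
        self.rss = rss
        #: per-branch rate magnitude: Euclidean norm over trait dimensions
        self.rates = np.linalg.norm(betas, axis=1)
        # variance-standardized rates: each trait's coefficients divided by
        # their per-branch null sd under BM, then norm over traits.  These
        # are approximately exchangeable across branches under the BM null,
        # which is what the permutation shift tests require.
        z = np.empty_like(betas)
        for j in range(betas.shape[1]):
            sd = model._rate_null_sd(float(lams[j]))
            z[:, j] = betas[:, j] / sd
        self.standardized_rates = np.linalg.norm(
            np.nan_to_num(z, nan=0.0), axis=1
        )
        self._anc = None

    @property
    def lam(self) -> float:
        return float(self.lambdas[0])

    @property
    def branches(self) -> list[int]:
        return self.model.path.branches

    def ancestral_states(self) -> np.ndarray:
        """Trait estimates at every node: root + accumulated branch change
        along the root-to-node path.  (n_nodes x traits; tips included.)"""
        if self._anc is None:
            tree = self.tree
            step = self.model.path.L.max(axis=0)[:, None] * self.coefs  # brlen*beta
            col = {v: i for i, v in enumerate(self.branches)}
            anc = np.tile(self.root_estimate, (tree.n_nodes, 1))
            for v in self.tree.postorder()[::-1]:  # preorder: parents first
                p = tree.parent[v]
                if p >= 0:
                    anc[v] = anc[p] + step[col[v]]
            self._anc = anc
        return self._anc

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.ancestral_states()[self.tree.tip_ids]

    def rates_frame(self) -> pd.DataFrame:
        tree = self.tree
        df = pd.DataFrame(self.coefs, columns=self.model.trait_names)
        df.insert(0, "node", self.branches)
        df.insert(1, "length", [tree.brlen[v] for v in self.branches])
        df["rate_norm"] = self.rates
        return df

    def summary(self) -> str:
        lines = [
            "Phylogenetic ridge regression",
            f"  tips: {self.tree.n_tips}   branches: {len(self.branches)}   "
            f"traits: {self.coefs.shape[1]}",
            "  lambda (per trait): "
            + ", ".join(format(l, ".4g") for l in self.lambdas),
            "  root estimate: "
            + ", ".join(format(r, ".4g") for r in self.root_estimate),
            f"  mean |rate|: {np.mean(self.rates):.4g}   "
            f"max |rate|: {np.max(self.rates):.4g}",
        ]
        return "\n".join(lines)

    # -- shift searches --------------------------------------------------
    def _clade_branch_cols(self) -> dict[int, np.ndarray]:
        """Internal node -> column indices of its branch + descendant branches."""
        tree = self.tree
        col = {v: i for i, v in enumerate(self.branches)}
        ch = tree.children()
        out: dict[int, np.ndarray] = {}
        members: dict[int, list[int]] = {}
        for v in tree.postorder():
            mine = [col[v]] if tree.parent[v] >= 0 else []
            for c in ch[v]:
                mine = mine + members[c]
            members[v] = mine
            if ch[v]:  # internal
                out[v] = np.array(mine, dtype=int)
        return out

    def simulate_null_rates(self, n_rand: int, seed: int) -> np.ndarray:
        """(B, n_rand) standardized branch rates under the fitted BM null.

        The null re-simulates Brownian motion on the tree with the GLS
        evolutionary rate estimated per trait from the data, then pushes
        every replicate through the same pipeline as the observed data (GCV
        penalty selection, ridge fit, variance standardization).  This
        preserves the correlation structure of branch-rate estimates, which
        a permutation of rates across branches does not.
        """
        model = self.model
        n, k = model.X.shape
        rng = np.random.default_rng(seed)
        C = model._C + 1e-10 * np.eye(n)
        Ci = np.linalg.inv(C)
        one = np.ones(n)
        Lc = np.linalg.cholesky(C)
        Q, mu = model._Q, model._mu
        scale = float(mu.sum()) / n
        grid = scale * np.logspace(-6, 3, 30)
        Qt1 = Q.T @ one
        z_all = np.zeros((self.model.path.L.shape[1], n_rand))
        acc = np.zeros_like(z_all)
        for j in range(k):
            y = model.X[:, j]
            gls_mu = float(one @ Ci @ y) / float(one @ Ci @ one)
            s2 = float((y - gls_mu) @ Ci @ (y - gls_mu)) / max(n - 1, 1)
            Ysim = gls_mu + np.sqrt(max(s2, 0.0)) * (Lc @ rng.standard_normal((n, n_rand)))
            Qty = Q.T @ Ysim  # (n, S)
            best_gcv = np.full(n_rand, np.inf)
            best_idx = np.zeros(n_rand, dtype=int)
            for gi, lam in enumerate(grid):
                d = (mu + lam)[:, None]
                winv_y = Qty / d
                winv_1 = (Qt1 / (mu + lam))[:, None]
                root = (Qt1 @ (Qty / (mu + lam)[:, None])) / float(Qt1 @ (Qt1 / (mu + lam)))
                core = (Qty - Qt1[:, None] * root[None, :]) / d
                rss = (lam**2) * (core * core).sum(axis=0)
                df = float(np.sum(mu / (mu + lam))) + 1.0
                gcv = n * rss / max(n - df, 1e-8) ** 2
                better = gcv < best_gcv
                best_gcv[better] = gcv[better]
                best_idx[better] = gi
            # compute standardized rates per chosen grid point
            for gi in np.unique(best_idx):
                lam = float(grid[gi])
                cols = best_idx == gi
                d = (mu + lam)[:, None]
                root = (Qt1 @ (Qty[:, cols] / (mu + lam)[:, None])) / float(
                    Qt1 @ (Qt1 / (mu + lam))
                )
                core = (Qty[:, cols] - Qt1[:, None] * root[None, :]) / d
                beta = model.path.L.T @ (Q @ core)
                sd = model._rate_null_sd(lam)
                acc[:, cols] = np.nan_to_num(beta / sd[:, None], nan=0.0)
            z_all += acc**2
        return np.sqrt(z_all)

    def search_shift_clade(
        self,
        min_clade: int = 1,
        n_rand: int = 1000,
        seed: int = 0,
        method: str = "simulation",
    ) -> list[RateShiftResult]:
        """Search for clade-specific shifts of the mean absolute rate.

        For every internal node whose clade holds at least ``min_clade``
        branches (background non-empty), the statistic is the difference of
        mean standardized absolute rates inside vs. outside.  Its null
        distribution comes from ``n_rand`` Brownian-motion re-simulations
        pushed through the same estimation pipeline (``method="simulation"``,
        the default — calibrated because it preserves the correlation of
        branch-rate estimates) or from random reassignments of the observed
        rates to branches (``method="permutation"``, anti-conservative under
        BM).  Two-tailed p-values are Bonferroni-adjusted over tested nodes.
        """
        if n_rand < 100:
            raise ValueError("n_rand must be >= 100 for stable p-values")
        rates = self.standardized_rates
        B = len(rates)
        clades = {
            v: cols
            for v, cols in self._clade_branch_cols().items()
            if len(cols) >= min_clade and len(cols) < B
        }
        if not clades:
            return []
        # contrast matrix: stat = a . rates with a = 1/n_in on clade, -1/n_out off
        A = np.full((len(clades), B), 0.0)
        units = list(clades)
        for row, v in enumerate(units):
            cols = clades[v]
            A[row, :] = -1.0 / (B - len(cols))
            A[row, cols] = 1.0 / len(cols)
        obs = A @ rates
        if method == "simulation":
            null = (A @ self.simulate_null_rates(n_rand, seed)).T  # (S, units)
            center = null.mean(axis=0)
            null = null - center[None, :]
            obs_c = obs - center
        elif method == "permutation":
            rng = np.random.default_rng(seed)
            perm = np.empty((n_rand, B))
            for r in range(n_rand):
                perm[r] = rng.permutation(rates)
            null = perm @ A.T  # (n_rand, n_units)
            obs_c = obs
        else:
            raise ValueError(f"unknown method {method!r}")
        exceed = (np.abs(null) >= np.abs(obs_c)[None, :] - 1e-12).sum(axis=0)
        p_raw = (1.0 + exceed) / (1.0 + n_rand)
        m = len(units)
        return [
            RateShiftResult(
                unit=v,
                rate_delta=float(obs[row]),
                p_raw=float(p_raw[row]),
                p_adjusted=float(min(1.0, p_raw[row] * m)),
                direction="slower" if obs_c[row] < 0 else "faster",
                n_branches=len(clades[v]),
            )
            for row, v in enumerate(units)
        ]

    def search_shift_state(
        self,
        tip_states: dict,
        n_rand: int = 1000,
        seed: int = 0,
        method: str = "simulation",
    ) -> list[RateShiftResult]:
        """State-specific ("sparse") rate-shift test.

        A branch carries a state iff *all* tips descending from it share
        that state; branches subtending a mixture belong to no state and are
        excluded from the comparison, which makes the two-state statistics
        exactly antisymmetric.  Each state is tested against the remaining
        pure-state branches, with the same simulation (default) or
        permutation null as :meth:`search_shift_clade`.
        """
        if n_rand < 100:
            raise ValueError("n_rand must be >= 100 for stable p-values")
        states = sorted(set(tip_states.values()))
        if len(states) < 2:
            raise ValueError("need >= 2 tip states")
        tree = self.tree
        desc = tree.tip_descendants()
        labels = tree.labels
        branch_state = []
        for v in self.branches:
            tip_sts = {tip_states[labels[t]] for t in desc[v]}
            branch_state.append(tip_sts.pop() if len(tip_sts) == 1 else None)
        branch_state = np.array(branch_state, dtype=object)
        pure = branch_state != None  # noqa: E711
        rates_p = self.standardized_rates[pure]
        st_p = branch_state[pure]
        if method == "simulation":
            null_rates = self.simulate_null_rates(n_rand, seed)[pure]
        rng = np.random.default_rng(seed)
        results = []
        for s in states:
            mask = st_p == s
            n_in, n_out = int(mask.sum()), int((~mask).sum())
            if n_in == 0 or n_out == 0:
                raise ValueError(f"state {s!r} has no pure branches to test")
            a = np.where(mask, 1.0 / n_in, -1.0 / n_out)
            obs = float(a @ rates_p)
            if method == "simulation":
                null = a @ null_rates  # (S,)
                center = float(null.mean())
                null = null - center
                obs_c = obs - center
            elif method == "permutation":
                null = np.empty(n_rand)
                for r in range(n_rand):
                    null[r] = a @ rng.permutation(rates_p)
                obs_c = obs
            else:
                raise ValueError(f"unknown method {method!r}")
            exceed = int((np.abs(null) >= abs(obs_c) - 1e-12).sum())
            p_raw = (1.0 + exceed) / (1.0 + n_rand)
            results.append(
                RateShiftResult(
                    unit=s,
                    rate_delta=obs,
                    p_raw=p_raw,
                    p_adjusted=min(1.0, p_raw * len(states)),
                    direction="slower" if obs_c < 0 else "faster",
                    n_branches=n_in,
                )
            )
        return results


# ---------------------------------------------------------------------------
# Functional wrappers (the operation-level surface)
# ---------------------------------------------------------------------------

def fit_ridge(tree: PhyloTree, y, lam: float = 0.0, taxa=None) -> RidgeRatesResults:
    return PhylogeneticRidge(tree, y, taxa=taxa).fit(lam=lam)


def select_lambda(tree: PhyloTree, y, taxa=None) -> float:
    model = PhylogeneticRidge(tree, y, taxa=taxa)
    return model.select_lambda(model.X[:, 0])


def search_shift_clade(results: RidgeRatesResults, **kw) -> list[RateShiftResult]:
    return results.search_shift_clade(**kw)


def search_shift_state(results: RidgeRatesResults, tip_states, **kw):
    return results.search_shift_state(tip_states, **kw)
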