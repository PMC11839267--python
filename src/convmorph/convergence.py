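"""Morphological convergence metrics with simulation/permutation inference.

Two complementary views of convergence for a designated habitat state:

* Stayton's distance-ratio metrics.  For a pair of putatively convergent
  tips, ``Dtip`` is their current phenotypic distance and ``Dmax`` the
  largest phenotypic distance their two lineages have reached at any point
  since the pair's MRCA (reconstructed ancestral states, tips and the MRCA
  included).  Then ``C1 = 1 - Dtip/Dmax`` (0 = none, 1 = complete
  convergence), ``C2 = Dmax - Dtip`` (absolute distance closed),
  ``C3 = C2 / L_tot.lineage`` (scaled by total change along both lineages),
  ``C4 = C2 / L_tot.clade`` (scaled by total change in the smallest clade
  containing all focal taxa).  Significance comes from re-simulating
  Brownian motion with the evolutionary rate matrix estimated from the data.

* Angles between species' displacement vectors from the reconstructed root
  state: same-habitat species pointing in similar directions (small mean
  angle theta, and small theta per unit patristic time) indicate
  convergence; significance from permuting the focal species set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .rates import PhylogeneticRidge
from .tree import PhyloTree, bm_covariance, patristic_matrix

__all__ = [
    "AncestralStates",
    "StaytonResult",
    "AngleResult",
    "reconstruct_ancestral",
    "stayton_c",
    "stayton_significance",
    "angle_convergence",
    "classify_habitat",
    "ConvergenceAnalysis",
    "ConvergenceResults",
]


@dataclass
class AncestralStates:
    """Per-node feature estimates on the tree (tips hold observed values)."""

    node_values: np.ndarray  # (n_nodes, k)
    taxa: list[str]
    tree: PhyloTree

    @property
    def root_state(self) -> np.ndarray:
        return self.node_values[self.tree.root]


@dataclass
class StaytonResult:
    C1: float
    C2: float
    C3: float
    C4: float
    p1: float = None  # type: ignore[assignment]
    p2: float = None  # type: ignore[assignment]
    p3: float = None  # type: ignore[assignment]
    p4: float = None  # type: ignore[assignment]
    n_sim: int = 0
    per_pair: pd.DataFrame = None  # type: ignore[assignment]


@dataclass
class AngleResult:
    theta_mean: float  # degrees
    theta_per_time: float  # degrees per unit patristic time
    p_theta: float
    p_theta_time: float
    n_perm: int

    @property
    def theta_mean_rad(self) -> float:
        return float(np.deg2rad(self.theta_mean))

    @property
    def theta_per_time_rad(self) -> float:
        return float(np.deg2rad(self.theta_per_time))


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------

def _reconstruction_operator(tree: PhyloTree, lam: float = 0.0) -> np.ndarray:
    """Linear map O with node_states = O @ tip_values (per feature).

    Uses the ridge path model: state(v) = root + sum of brlen*beta over the
    root-to-v path; at lam = 0 the fit interpolates, so tip rows of O pick
    out the observed values exactly.
    """
    model = PhylogeneticRidge(tree, np.zeros(tree.n_tips))
    n = tree.n_tips
    Q, mu = model._Q, model._mu
    d = mu + lam
    floor = 1e-12 * max(mu.max(), 1.0)
    d = np.where(d < floor, floor, d)
    Minv = Q @ np.diag(1.0 / d) @ Q.T
    one = np.ones(n)
    w = Minv @ one / float(one @ Minv @ one)  # root = w' y
    core = Minv @ (np.eye(n) - np.outer(one, w))  # (M+lam)^-1 (y - root 1)
    beta_op = model.path.L.T @ core  # beta = beta_op @ y
    # path accumulation: node x branch indicator times brlen
    col = {v: i for i, v in enumerate(model.path.branches)}
    P = np.zeros((tree.n_nodes, len(model.path.branches)))
    for v in range(tree.n_nodes):
        for u in tree.path_to_root(v):
            if tree.parent[u] >= 0:
                P[v, col[u]] = tree.brlen[u]
    return np.outer(np.ones(tree.n_nodes), w) + P @ beta_op


def reconstruct_ancestral(tree: PhyloTree, X, lam: float = 0.0) -> AncestralStates:
    """Ancestral feature estimates at every node via the ridge path model."""
    if isinstance(X, pd.DataFrame):
        X = X.loc[tree.taxa].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != tree.n_tips:
        X = X.T
    O = _reconstruction_operator(tree, lam)
    return AncestralStates(node_values=O @ X, taxa=tree.taxa, tree=tree)


# ---------------------------------------------------------------------------
# Stayton C1-C4
# ---------------------------------------------------------------------------

class _StaytonEngine:
    """Precomputed index structure for fast repeated C1-C4 evaluation."""

    def __init__(self, tree: PhyloTree, focal: list[str]):
        taxa = tree.taxa
        missing = [s for s in focal if s not in taxa]
        if missing:
            raise ValueError(f"focal species absent from tree: {missing}")
        if len(focal) < 2:
            raise ValueError("need >= 2 focal species")
        self.tree = tree
        self.focal = list(focal)
        tip_of = {tree.labels[t]: t for t in tree.tip_ids}
        ids = [tip_of[s] for s in focal]
        self.pairs = []  # (tip_i, tip_j, lineage_i nodes, lineage_j nodes)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = ids[a], ids[b]
                m = tree.mrca(i, j)
                lin_i = []  # nodes on m -> i inclusive
                for u in tree.path_to_root(i):
                    lin_i.append(u)
                    if u == m:
                        break
                lin_j = []
                for u in tree.path_to_root(j):
                    lin_j.append(u)
                    if u == m:
                        break
                self.pairs.append((i, j, np.array(lin_i), np.array(lin_j)))
        # smallest clade containing all focal taxa
        m_all = ids[0]
        for t in ids[1:]:
            m_all = tree.mrca(m_all, t)
        desc_nodes = []
        ch = tree.children()
        stack = list(ch[m_all])
        while stack:
            v = stack.pop()
            desc_nodes.append(v)
            stack.extend(ch[v])
        self.clade_nodes = np.array(desc_nodes, dtype=int)  # branches below MRCA

    def metrics(self, states: np.ndarray) -> tuple[float, float, float, float]:
        """C1-C4 from an (n_nodes, k) state matrix; pairwise-averaged."""
        tree = self.tree
        parent = tree.parent
        step = states - states[np.maximum(parent, 0)]  # branch change vectors
        clade_tot = float(
            np.linalg.norm(step[self.clade_nodes], axis=1).sum()
        )
        c1s, c2s, c3s, c4s = [], [], [], []
        for i, j, lin_i, lin_j in self.pairs:
            dtip = float(np.linalg.norm(states[i] - states[j]))
            dmax = float(cdist(states[lin_i], states[lin_j]).max())
            if dmax <= 0:
                continue
            c2 = dmax - dtip
            lin_tot = float(
                np.linalg.norm(step[lin_i[:-1]], axis=1).sum()
                + np.linalg.norm(step[lin_j[:-1]], axis=1).sum()
            )
            c1s.append(1.0 - dtip / dmax)
            c2s.append(c2)
            c3s.append(c2 / lin_tot if lin_tot > 0 else np.nan)
            c4s.append(c2 / clade_tot if clade_tot > 0 else np.nan)
        if not c1s:
            warnings.warn("Dmax = 0 for all focal pairs; C metrics undefined")
            return (np.nan,) * 4
        return (
            float(np.mean(c1s)),
            float(np.mean(c2s)),
            float(np.nanmean(c3s)),
            float(np.nanmean(c4s)),
        )

    def per_pair_frame(self, states: np.ndarray) -> pd.DataFrame:
        rows = []
        labels = self.tree.labels
        for i, j, lin_i, lin_j in self.pairs:
            dtip = float(np.linalg.norm(states[i] - states[j]))
            dmax = float(cdist(states[lin_i], states[lin_j]).max())
            rows.append(
                {
                    "species_1": labels[i],
                    "species_2": labels[j],
                    "Dtip": dtip,
                    "Dmax": dmax,
                    "C1": 1.0 - dtip / dmax if dmax > 0 else np.nan,
                    "C2": dmax - dtip,
                }
            )
        return pd.DataFrame(rows)


def _as_matrix(X, tree: PhyloTree) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.loc[tree.taxa].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def stayton_c(tree: PhyloTree, X, focal, anc: AncestralStates | None = None) -> StaytonResult:
    """Point estimates of C1-C4 for the focal species set."""
    Xm = _as_matrix(X, tree)
    if anc is None:
        anc = reconstruct_ancestral(tree, Xm)
    eng = _StaytonEngine(tree, list(focal))
    c1, c2, c3, c4 = eng.metrics(anc.node_values)
    return StaytonResult(
        C1=c1, C2=c2, C3=c3, C4=c4, per_pair=eng.per_pair_frame(anc.node_values)
    )


def _rate_matrix(tree: PhyloTree, Xm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS evolutionary rate matrix and root state under BM."""
    C = bm_covariance(tree).C
    Ci = np.linalg.inv(C + 1e-10 * np.eye(len(C)))
    one = np.ones(len(C))
    mu = (one @ Ci @ Xm) / float(one @ Ci @ one)
    D = Xm - mu
    R = D.T @ Ci @ D / max(len(C) - 1, 1)
    return R, mu


def stayton_significance(
    tree: PhyloTree, X, focal, n_sim: int = 1000, seed: int = 0
) -> StaytonResult:
    """C1-C4 with p-values from a Brownian-motion null.

    The null re-simulates multivariate BM on the tree with the rate matrix
    estimated from the data (GLS / independent-contrasts covariance) and
    recomputes the metrics for the same focal set; ``p_k = (1 + #{sim >=
    obs}) / (1 + n_sim)``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    Xm = _as_matrix(X, tree)
    eng = _StaytonEngine(tree, list(focal))
    O = _reconstruction_operator(tree)
    obs = eng.metrics(O @ Xm)
    R, mu = _rate_matrix(tree, Xm)
    C = bm_covariance(tree).C
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    # matrix square root of R (eigen; R is PSD)
    w, V = np.linalg.eigh(R)
    Rh = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    rng = np.random.default_rng(seed)
    n, k = Xm.shape
    exceed = np.zeros(4)
    valid = np.zeros(4)
    for _ in range(n_sim):
        Y = mu + Lc @ rng.standard_normal((n, k)) @ Rh
        sim = eng.metrics(O @ Y)
        for m in range(4):
            if np.isfinite(sim[m]) and np.isfinite(obs[m]):
                valid[m] += 1
                if sim[m] >= obs[m] - 1e-12:
                    exceed[m] += 1
    p = (1.0 + exceed) / (1.0 + valid)
    return StaytonResult(
        C1=obs[0], C2=obs[1], C3=obs[2], C4=obs[3],
        p1=float(p[0]), p2=float(p[1]), p3=float(p[2]), p4=float(p[3]),
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# Angular convergence
# ---------------------------------------------------------------------------

def _angle_matrix(V: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    cos = (V @ V.T) / np.outer(norms, norms)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def angle_convergence(
    tree: PhyloTree,
    X,
    focal,
    n_perm: int = 1000,
    seed: int = 0,
    patristic: np.ndarray | None = None,
    center: str = "root",
) -> AngleResult:
    """Mean pairwise angle among focal species, raw and per unit time.

    Feature vectors are centered at the reconstructed root state (so angles
    measure the *direction* of evolutionary displacement); ``center="mean"``
    uses the grand mean instead.  One-tailed permutation p: the fraction of
    random same-size species sets whose mean angle is <= the observed one
    (small angles = convergent).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Xm = _as_matrix(X, tree)
    taxa = tree.taxa
    focal = list(focal)
    missing = [s for s in focal if s not in taxa]
    if missing:
        raise ValueError(f"focal species absent from tree: {missing}")
    if center == "root":
        c = reconstruct_ancestral(tree, Xm).root_state
    else:
        c = Xm.mean(axis=0)
    V = Xm - c
    norms = np.linalg.norm(V, axis=1)
    ok = norms > 1e-12
    if not np.all(ok):
        warnings.warn(
            f"excluding zero-displacement species: {[t for t, o in zip(taxa, ok) if not o]}"
        )
    idx_ok = np.nonzero(ok)[0]
    ang = _angle_matrix(V[idx_ok])
    if patristic is None:
        patristic = patristic_matrix(tree)
    pat = patristic[np.ix_(idx_ok, idx_ok)]
    pos = {taxa[i]: p for p, i in enumerate(idx_ok)}
    fidx = np.array([pos[s] for s in focal if s in pos])
    if len(fidx) < 2:
        raise ValueError("fewer than 2 usable focal species")
    iu = np.triu_indices(len(fidx), 1)
    obs_theta = float(ang[np.ix_(fidx, fidx)][iu].mean())
    with np.errstate(divide="ignore"):
        rate = ang / np.where(pat > 0, pat, np.inf)
    obs_rate = float(rate[np.ix_(fidx, fidx)][iu].mean())
    rng = np.random.default_rng(seed)
    m = len(fidx)
    le_theta = le_rate = 0
    for _ in range(n_perm):
        sub = rng.choice(len(idx_ok), size=m, replace=False)
        iu2 = np.triu_indices(m, 1)
        th = ang[np.ix_(sub, sub)][iu2].mean()
        rt = rate[np.ix_(sub, sub)][iu2].mean()
        le_theta += th <= obs_theta + 1e-12
        le_rate += rt <= obs_rate + 1e-12
    return AngleResult(
        theta_mean=obs_theta,
        theta_per_time=obs_rate,
        p_theta=(1.0 + le_theta) / (1.0 + n_perm),
        p_theta_time=(1.0 + le_rate) / (1.0 + n_perm),
        n_perm=n_perm,
    )


def classify_habitat(mean_temp: float, threshold: float = 6.0):
    """Alpine iff mean ground temperature <= threshold (degC), else riparian.

    The study's thresholds are 6 and 7 degC (treeline ground temperature);
    other values are allowed with a warning.  Missing temperature -> None.
    """
    if threshold not in (6.0, 7.0):
        warnings.warn(f"nonstandard alpine threshold {threshold} degC")
    if mean_temp is None or (isinstance(mean_temp, float) and np.isnan(mean_temp)):
        return None
    return "alpine" if mean_temp <= threshold else "riparian"


# ---------------------------------------------------------------------------
# Model-style wrapper
# ---------------------------------------------------------------------------

class ConvergenceAnalysis:
    """Convergence of a focal habitat state in a feature space.

    Parameters
    ----------
    tree : PhyloTree
    X : DataFrame (species x features)
    habitat : Series of habitat states per species (or a mapping)
    state : the putatively convergent state ("alpine" or "riparian")
    """

    def __init__(self, tree: PhyloTree, X, habitat, state: str):
        self.tree = tree
        self.X = X
        hab = habitat if isinstance(habitat, pd.Series) else pd.Series(habitat)
        self.focal = [s for s in tree.taxa if hab.get(s) == state]
        if len(self.focal) < 2:
            raise ValueError(f"fewer than 2 species in state {state!r}")
        self.state = state

    def fit(self, n_sim: int = 1000, n_perm: int = 1000, seed: int = 0):
        st = stayton_significance(self.tree, self.X, self.focal, n_sim=n_sim, seed=seed)
        an = angle_convergence(self.tree, self.X, self.focal, n_perm=n_perm, seed=seed + 1)
        return ConvergenceResults(self, st, an)


class ConvergenceResults:
    def __init__(self, model: ConvergenceAnalysis, stayton: StaytonResult, angle: AngleResult):
        self.model = model
        self.stayton = stayton
        self.angle = angle

    def summary(self) -> str:
        s, a = self.stayton, self.angle
        return "\n".join(
            [
                f"Convergence of state {self.model.state!r} "
                f"({len(self.model.focal)} species)",
                f"  C1 = {s.C1:.4g} (p = {s.p1:.4g})   C2 = {s.C2:.4g} (p = {s.p2:.4g})",
                f"  C3 = {s.C3:.4g} (p = {s.p3:.4g})   C4 = {s.C4:.4g} (p = {s.p4:.4g})",
                f"  theta = {a.theta_mean:.4g} deg ({a.theta_mean_rad:.4g} rad), "
                f"p = {a.p_theta:.4g}",
                f"  theta/time = {a.theta_per_time:.4g} deg/time, p = {a.p_theta_time:.4g}",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        s, a = self.stayton, self.angle
        return pd.DataFrame(
            [
                {
                    "state": self.model.state,
                    "C1": s.C1, "p1": s.p1,
                    "C2": s.C2, "p2": s.p2,
                    "C3": s.C3, "p3": s.p3,
                    "C4": s.C4, "p4": s.p4,
                    "theta_deg": a.theta_mean,
                    "theta_rad": a.theta_mean_rad,
                    "theta_per_time_deg": a.theta_per_time,
                    "p_theta": a.p_theta,
                    "p_theta_time": a.p_theta_time,
                }
            ]
        )
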