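"""Synthetic data with the statistical structure the analysis assumes.

Generates (i) ultrametric Yule trees standing in for the beetle phylogeny,
(ii) a Brownian thermal variable thresholded into alpine/riparian habitat
states, (iii) multivariate traits evolving by Brownian motion or by
regime-dependent Ornstein-Uhlenbeck attraction toward habitat-specific
optima, (iv) specimen-level measurements with within-species noise, and
(v) parametric beetle-like outlines (superellipses) whose axis ratio and
angularity covary with the simulated traits.  Every output is a pure
function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outlines import Outline
from .tree import PhyloTree

__all__ = [
    "LINEAR_TRAITS",
    "SimConfig",
    "SimTruth",
    "simulate_yule_tree",
    "simulate_bm",
    "simulate_convergent",
    "simulate_specimens",
    "generate_outline",
    "simulate_outlines",
    "habitat_table",
]

#: measured linear traits, in the trait-table column order
LINEAR_TRAITS = ("scape_length", "elytral_length", "elytral_ratio", "pronotal_ratio")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the empirical setting: 79 species, ~17 specimens per
    species, four linear traits (antennal scape length and elytral length in
    mm, elytral and pronotal ratios dimensionless), a Brownian thermal
    variable thresholded at 6 degC to define alpine habitat, and moderate
    OU attraction toward habitat-specific optima.
    """

    n_species: int = 79
    seed: int = 0
    birth_rate: float = 1.0
    root_state: tuple = (0.8, 6.0, 1.8, 1.5)
    sigma2: tuple = (0.02, 1.0, 0.04, 0.04)  # per trait, per unit tree time
    regime_pull: float = 1.0  # OU alpha; 0 = pure BM
    optima: dict = field(
        default_factory=lambda: {
            # alpine: larger-bodied, rounder; riparian: smaller, more angular
            "alpine": (0.8, 7.5, 1.6, 1.4),
            "riparian": (0.8, 5.0, 2.0, 1.6),
        }
    )
    temp_sigma2: float = 4.0  # degC^2 per unit tree time
    temp_root: float = 5.5  # degC (slight alpine majority, as in the assemblage)
    threshold: float = 6.0  # degC; alpine iff mean temp <= threshold
    n_specimens: int = 17
    noise_sd: tuple = (0.05, 0.30, 0.05, 0.05)  # within-species measurement sd
    #: trait -> weight mapping traits to outline angularity (per structure)
    outline_params: dict = field(
        default_factory=lambda: {
            "pronotum": {"pronotal_ratio": 2.0},
            "elytron": {"elytral_ratio": 2.5},
        }
    )
    n_outline_points: int = 120
    outline_noise: float = 0.0
    #: max segment length (time units) for regime switching along branches;
    #: None = 1/50 of tree height, so regimes track the thermal variable
    #: finely enough that a tip's recent regime matches its habitat label
    segment_length: float | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.regime_pull < 0 or self.temp_sigma2 < 0:
            raise ValueError("rates must be >= 0")
        if any(s < 0 for s in self.sigma2):
            raise ValueError("sigma2 must be >= 0 elementwise")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    tree: PhyloTree
    species_temps: pd.Series  # degC per species
    habitat: pd.Series  # "alpine" | "riparian" per species
    species_means: pd.DataFrame  # species x trait
    branch_rates_true: np.ndarray  # per non-root-node rate multiplier
    convergent: bool
    config: SimConfig


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n`` tips.

    Time runs from the root split (2 lineages) to the present; while k
    lineages are extant the next split waits Exp(k * birth_rate), and a
    final Exp(n * birth_rate) epoch precedes the present, so the expected
    root height is ``sum_{k=2..n} 1/(k * birth_rate)``.
    """
    if n < 2:
        raise ValueError("need n >= 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # time each lineage began
    active = [1, 2]
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (birth_rate * k))
        j = active.pop(rng.integers(len(active)))
        for _ in range(2):
            parent.append(j)
            birth.append(t)
            active.append(len(parent) - 1)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n))
    brlen = np.zeros(len(parent))
    labels: list = [None] * len(parent)
    support: list = [None] * len(parent)
    tip_no = 0
    active_set = set(active)
    for v in range(1, len(parent)):
        end = t if v in active_set else birth[
            next(c for c in range(len(parent)) if parent[c] == v)
        ]
        brlen[v] = end - birth[v]
    width = len(str(n))
    for v in sorted(active_set):
        tip_no += 1
        labels[v] = f"sp{tip_no:0{width}d}"
    tree = PhyloTree(np.array(parent), brlen, tuple(labels), tuple(support))
    # renumber to preorder via a write-free rebuild (children lists preserved)
    return _to_preorder(tree)


def _to_preorder(tree: PhyloTree) -> PhyloTree:
    ch = tree.children()
    order: list[int] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(ch[v]))
    remap = {old: new for new, old in enumerate(order)}
    parent = np.array(
        [remap[int(tree.parent[o])] if tree.parent[o] >= 0 else -1 for o in order]
    )
    return PhyloTree(
        parent,
        tree.brlen[order],
        tuple(tree.labels[o] for o in order),
        tuple(tree.support[o] for o in order),
    )


# ---------------------------------------------------------------------------
# Trait evolution
# ---------------------------------------------------------------------------

def simulate_bm(
    tree: PhyloTree,
    sigma2,
    root_state,
    seed: int = 0,
    n_reps: int | None = None,
    branch_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Brownian motion on the tree: each branch adds N(0, sigma2 * brlen).

    Returns species means as an ``(n_tips, k)`` array in ``tree.taxa``
    order, or ``(n_reps, n_tips, k)`` when ``n_reps`` is given.
    ``branch_scale`` multiplies sigma2 branch-wise (rate-shift scenarios).
    """
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    root_state = np.atleast_1d(np.asarray(root_state, dtype=float))
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be >= 0")
    k = len(sigma2)
    rng = np.random.default_rng(seed)
    branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    bl = tree.brlen[branches]
    scale = np.ones(len(branches)) if branch_scale is None else np.asarray(branch_scale)
    sd = np.sqrt(np.outer(bl * scale, sigma2))  # (B, k)
    desc = tree.tip_descendants()
    tips = tree.tip_ids
    pos = {t: i for i, t in enumerate(tips)}
    P = np.zeros((len(tips), len(branches)))
    for col, v in enumerate(branches):
        P[[pos[t] for t in desc[v]], col] = 1.0
    reps = 1 if n_reps is None else n_reps
    inc = rng.standard_normal((reps, len(branches), k)) * sd[None, :, :]
    out = root_state[None, None, :] + np.einsum("ib,rbk->rik", P, inc)
    return out[0] if n_reps is None else out


def _ou_step(x, opt, alpha, sigma2, t, z):
    """Exact OU transition over time t (alpha = 0 is the BM limit)."""
    if alpha > 0:
        decay = np.exp(-alpha * t)
        var = sigma2 * (1.0 - np.exp(-2.0 * alpha * t)) / (2.0 * alpha)
        return opt + (x - opt) * decay + np.sqrt(var) * z
    return x + np.sqrt(sigma2 * t) * z


def simulate_convergent(tree: PhyloTree, config: SimConfig) -> SimTruth:
    """Regime-dependent trait evolution with habitat set by a thermal BM.

    The thermal variable evolves by Brownian motion from ``temp_root``.
    Branches are divided into short segments; a segment's regime is alpine
    iff its midpoint temperature is at or below the threshold, and traits
    follow the exact OU transition toward that regime's optimum with
    strength ``regime_pull`` (0 reduces to BM).  Regimes are therefore
    phylogenetically clustered but flip wherever the thermal variable
    crosses the threshold, producing occasional convergent states.
    """
    cfg = config
    for s in ("alpine", "riparian"):
        if s not in cfg.optima:
            raise ValueError(f"optima missing state {s!r}")
    rng = np.random.default_rng(cfg.seed)
    n_nodes = tree.n_nodes
    preorder = tree.postorder()[::-1]
    seg_max = cfg.segment_length or tree.height() / 50.0
    k = len(cfg.sigma2)
    sigma2 = np.asarray(cfg.sigma2, dtype=float)
    sig_t = np.sqrt(cfg.temp_sigma2)
    alpha = cfg.regime_pull
    opt = {s: np.asarray(cfg.optima[s], dtype=float) for s in cfg.optima}
    temps = np.zeros(n_nodes)
    temps[tree.root] = cfg.temp_root
    X = np.zeros((n_nodes, k))
    X[tree.root] = np.asarray(cfg.root_state, dtype=float)
    branch_state = {}
    for v in preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        t_total = tree.brlen[v]
        n_seg = max(1, int(np.ceil(t_total / seg_max))) if t_total > 0 else 1
        dt = t_total / n_seg
        temp = temps[p]
        x = X[p].copy()
        state = None
        for _ in range(n_seg):
            temp_next = temp + sig_t * np.sqrt(dt) * rng.standard_normal()
            mid = 0.5 * (temp + temp_next)
            state = "alpine" if mid <= cfg.threshold else "riparian"
            x = _ou_step(x, opt[state], alpha, sigma2, dt, rng.standard_normal(k))
            temp = temp_next
        temps[v] = temp
        X[v] = x
        branch_state[v] = state  # regime of the segment ending at v
    tips = tree.tip_ids
    taxa = tree.taxa
    species_temps = pd.Series(temps[tips], index=taxa, name="mean_temp")
    habitat = pd.Series(
        np.where(species_temps <= cfg.threshold, "alpine", "riparian"),
        index=taxa,
        name="habitat",
    )
    means = pd.DataFrame(X[tips], index=taxa, columns=list(LINEAR_TRAITS)[:k])
    branches = [v for v in range(n_nodes) if tree.parent[v] >= 0]
    return SimTruth(
        tree=tree,
        species_temps=species_temps,
        habitat=habitat,
        species_means=means,
        branch_rates_true=np.ones(len(branches)),
        convergent=alpha > 0,
        config=cfg,
    )


def simulate_specimens(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Specimen table: species mean + N(0, noise_sd^2), sexes alternating."""
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    noise = np.asarray(cfg.noise_sd, dtype=float)
    rows = []
    for sp, mean in truth.species_means.iterrows():
        vals = mean.to_numpy()[None, :] + rng.standard_normal(
            (cfg.n_specimens, len(mean))
        ) * noise[None, : len(mean)]
        for i in range(cfg.n_specimens):
            rows.append(
                {
                    "species": sp,
                    "specimen_id": f"{sp}_{i + 1:02d}",
                    "sex": "M" if i % 2 == 0 else "F",
                    **dict(zip(truth.species_means.columns, vals[i])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outlines
# ---------------------------------------------------------------------------

def generate_outline(
    trait_vector,
    structure: str = "pronotum",
    n_points: int = 120,
    seed: int = 0,
    noise: float = 0.0,
    label: str = "",
) -> Outline:
    """Superellipse outline: ``|x/ratio|^m + |y|^m = 1`` with ``m = 2 +
    angularity``.  ``trait_vector`` needs keys ``ratio`` (length:width > 0)
    and ``angularity`` (>= 0; 0 gives an exact ellipse, larger values give
    squarer, more angular outlines with power moving into harmonic 3).
    """
    ratio = float(trait_vector["ratio"])
    ang = float(trait_vector["angularity"])
    if ratio <= 0:
        raise ValueError("length:width ratio must be > 0")
    if ang < 0:
        ang = 0.0
    m = 2.0 + ang
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    co, si = np.cos(th), np.sin(th)
    x = ratio * np.sign(co) * np.abs(co) ** (2.0 / m)
    y = np.sign(si) * np.abs(si) ** (2.0 / m)
    if noise > 0:
        rng = np.random.default_rng(seed)
        r = 1.0 + noise * rng.standard_normal(n_points)
        x, y = x * r, y * r
    return Outline(np.column_stack([x, y]), label=label, structure=structure)


def _angularity(cfg: SimConfig, structure: str, values: pd.Series) -> float:
    weights = cfg.outline_params.get(structure, {})
    root = dict(zip(LINEAR_TRAITS, cfg.root_state))
    z = sum(w * (values[t] - root[t]) for t, w in weights.items() if t in values)
    return float(max(0.0, z))


def simulate_outlines(
    truth: SimTruth, specimens: pd.DataFrame, config: SimConfig | None = None
) -> list[Outline]:
    """One outline per specimen per structure, deformed by its trait values."""
    cfg = config or truth.config
    outlines = []
    for i, row in specimens.iterrows():
        for structure, ratio_trait in (
            ("pronotum", "pronotal_ratio"),
            ("elytron", "elytral_ratio"),
        ):
            outlines.append(
                generate_outline(
                    {
                        "ratio": max(row[ratio_trait], 0.2),
                        "angularity": _angularity(cfg, structure, row),
                    },
                    structure=structure,
                    n_points=cfg.n_outline_points,
                    seed=cfg.seed + 7919 * (i + 1),
                    noise=cfg.outline_noise,
                    label=row["specimen_id"],
                )
            )
    return outlines


# ---------------------------------------------------------------------------
# Habitat table
# ---------------------------------------------------------------------------

def habitat_table(truth: SimTruth, seed: int | None = None) -> pd.DataFrame:
    """Per-species habitat variables with realistic cross-correlations.

    Elevation is strongly anti-correlated with ground temperature (so the
    collinearity screen at |r| < 0.75 has something to drop), solar/vapor
    track temperature loosely, and substrate class follows habitat state.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    t = truth.species_temps.to_numpy()
    n = len(t)
    elev = 2600.0 - 180.0 * t + 80.0 * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "species": truth.species_temps.index,
            "mean_temp": t,
            "max_temp": t + 9.0 + 1.5 * rng.standard_normal(n),
            "min_temp": t - 9.0 + 1.5 * rng.standard_normal(n),
            "elevation": elev,
            "latitude": 46.0 + 6.0 * rng.standard_normal(n),
            "longitude": -121.0 + 8.0 * rng.standard_normal(n),
            "solar": 14000.0 + 350.0 * t + 900.0 * rng.standard_normal(n),
            "vapor": 0.75 + 0.05 * t + 0.08 * rng.standard_normal(n),
            "precip": 1400.0 + 420.0 * rng.standard_normal(n),
            "wind": 3.0 + 0.8 * np.abs(rng.standard_normal(n)),
            "substrate": np.where(
                truth.habitat.to_numpy() == "alpine", "talus", "gravel"
            ),
        }
    )
    return df
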