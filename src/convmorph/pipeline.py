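"""End-to-end orchestration: simulate -> EFA -> morphospace -> rates ->
convergence, with one YAML config, per-stage seeds derived from a master
seed, config-hash caching, and CSV outputs throughout.

Each stage reads its inputs from, and writes its outputs to, the run output
directory; a stage is skipped on rerun when its config hash and outputs are
unchanged, so deleting one stage's outputs recomputes only that stage and
its descendants.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence as conv
from . import morphospace as morph
from . import outlines as efa
from . import rates as rates_mod
from . import simulate as sim
from . import tree as treeio

log = logging.getLogger("convmorph")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

TRAIT_SETS = ("linear", "pronotal_shape", "elytral_shape")


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    sim: dict | None = field(default_factory=dict)  # SimConfig overrides
    inputs: dict | None = None  # {tree, traits, habitat, outlines} paths
    thresholds: tuple = (6.0, 7.0)
    n_rand: int = 1000
    n_sim: int = 1000
    n_perm: int = 1000
    k_range: tuple = (1, 10)
    n_init: int = 10
    efa_power: float = 0.99
    shape_var: float = 0.95
    min_clade: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sim is None and self.inputs is None:
            raise ValueError("config needs either a sim block or input paths")
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")

    def stage_seed(self, stage: int) -> int:
        return (self.seed * 1_000_003 + 97 * stage + 13) % (2**31)

    def canonical(self) -> str:
        # outdir and log level are execution details, not analysis content
        skip = {"outdir", "log_level"}
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k not in skip}
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    outdir: str
    config_hash: str
    manifest: dict  # stage -> list of file names
    tables: dict  # name -> DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {"outdir": self.outdir, "config_hash": self.config_hash,
             "manifest": self.manifest},
            indent=2,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("thresholds", "k_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Stage plumbing
# ---------------------------------------------------------------------------

def _stage_fresh(out: Path, stage: str, key: str, files: list[str]) -> bool:
    hf = out / f".{stage}.hash"
    if not hf.exists() or hf.read_text() != key:
        return False
    return all((out / f).exists() and (out / f).stat().st_size > 0 for f in files)


def _stage_done(out: Path, stage: str, key: str) -> None:
    (out / f".{stage}.hash").write_text(key)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_data(cfg: RunConfig, out: Path) -> list[str]:
    """Simulate (or stage in) tree, traits, habitat, outlines."""
    files = ["tree.nwk", "traits.csv", "habitat.csv", "outlines.csv"]
    key = cfg.config_hash + ":data"
    if _stage_fresh(out, "data", key, files):
        log.info("data: cached")
        return files
    if cfg.inputs:
        import shutil

        for name, dst in zip(("tree", "traits", "habitat", "outlines"), files):
            shutil.copyfile(cfg.inputs[name], out / dst)
    else:
        overrides = dict(cfg.sim or {})
        overrides.setdefault("seed", cfg.stage_seed(0))
        sc = sim.SimConfig(**overrides)
        tree = sim.simulate_yule_tree(sc.n_species, sc.birth_rate, seed=sc.seed)
        truth = sim.simulate_convergent(tree, sc)
        specimens = sim.simulate_specimens(truth, sc)
        habitat = sim.habitat_table(truth)
        outl = sim.simulate_outlines(truth, specimens, sc)
        (out / "tree.nwk").write_text(treeio.write_newick(tree) + "\n")
        specimens.to_csv(out / "traits.csv", index=False)
        habitat.to_csv(out / "habitat.csv", index=False)
        rows = []
        for o in outl:
            for i, (x, y) in enumerate(o.points):
                rows.append((o.label, o.structure, i, x, y))
        pd.DataFrame(
            rows, columns=["label", "structure", "point_index", "x", "y"]
        ).to_csv(out / "outlines.csv", index=False)
    # referential integrity
    tree = treeio.read_newick_file(out / "tree.nwk")
    traits = pd.read_csv(out / "traits.csv")
    bad = sorted(set(traits["species"]) - set(tree.taxa))
    if bad:
        raise ValueError(f"species in traits but not in tree: {bad}")
    _stage_done(out, "data", key)
    log.info("data: wrote %s", files)
    return files


def stage_efa(cfg: RunConfig, out: Path) -> list[str]:
    """Decompose + normalize outlines; species-level shape PC scores."""
    files = ["coefficients.csv", "shape_scores_pronotum.csv",
             "shape_scores_elytron.csv"]
    key = cfg.config_hash + ":efa:" + _file_hash(out / "outlines.csv")
    if _stage_fresh(out, "efa", key, files):
        log.info("efa: cached")
        return files
    pts = pd.read_csv(out / "outlines.csv")
    traits = pd.read_csv(out / "traits.csv")
    spec2sp = dict(zip(traits["specimen_id"], traits["species"]))
    coef_rows = []
    for structure, grp in pts.groupby("structure"):
        outl = [
            efa.Outline(
                g.sort_values("point_index")[["x", "y"]].to_numpy(),
                label=label,
                structure=structure,
            )
            for label, g in grp.groupby("label")
        ]
        n_h = efa.choose_harmonics(outl, cfg.efa_power)
        coefs = [efa.efa_normalize(efa.efa_decompose(o, n_h)) for o in outl]
        for c in coefs:
            for n, (a, b, cc, d) in enumerate(c.harmonics, start=1):
                coef_rows.append((c.label, structure, n, a, b, cc, d))
        # species-mean coefficient vectors -> PCA scores
        by_sp: dict[str, list[np.ndarray]] = {}
        for c in coefs:
            by_sp.setdefault(spec2sp.get(c.label, c.label), []).append(c.flatten())
        species = sorted(by_sp)
        M = np.array([np.mean(by_sp[s], axis=0) for s in species])
        U, s_, Vt = np.linalg.svd(M - M.mean(0), full_matrices=False)
        eig = s_**2
        frac = np.cumsum(eig) / eig.sum()
        keep = int(np.searchsorted(frac, cfg.shape_var - 1e-12)) + 1
        scores = pd.DataFrame(
            (U * s_)[:, :keep],
            index=pd.Index(species, name="species"),
            columns=[f"PC{i + 1}" for i in range(keep)],
        )
        scores.to_csv(out / f"shape_scores_{structure}.csv")
    pd.DataFrame(
        coef_rows, columns=["label", "structure", "n", "a", "b", "c", "d"]
    ).to_csv(out / "coefficients.csv", index=False)
    _stage_done(out, "efa", key)
    log.info("efa: wrote %s", files)
    return files


def _load_feature_sets(out: Path) -> dict[str, pd.DataFrame]:
    traits = pd.read_csv(out / "traits.csv")
    linear = traits.groupby("species")[list(sim.LINEAR_TRAITS)].mean()
    pron = pd.read_csv(out / "shape_scores_pronotum.csv", index_col="species")
    elyt = pd.read_csv(out / "shape_scores_elytron.csv", index_col="species")
    return {"linear": linear, "pronotal_shape": pron, "elytral_shape": elyt}


def stage_morphospace(cfg: RunConfig, out: Path) -> list[str]:
    files = ["clusters.csv", "cluster_tests.csv", "models.csv"]
    key = cfg.config_hash + ":morphospace:" + _file_hash(out / "traits.csv")
    if _stage_fresh(out, "morphospace", key, files):
        log.info("morphospace: cached")
        return files
    tree = treeio.read_newick_file(out / "tree.nwk")
    feats = _load_feature_sets(out)
    habitat = pd.read_csv(out / "habitat.csv").set_index("species")
    habitat = habitat.loc[feats["linear"].index]
    cov = treeio.bm_covariance(tree)
    # align feature rows to tree taxa order
    feats = {k: v.loc[cov.taxa] for k, v in feats.items()}
    habitat = habitat.loc[cov.taxa]
    # habitat fixed effects: latitude & elevation forced first, then screen
    ordered = ["latitude", "elevation"] + [
        c for c in habitat.select_dtypes(include=[np.number]).columns
        if c not in ("latitude", "elevation")
    ]
    kept = morph.screen_collinear(habitat[ordered])
    hx = habitat[kept]
    cluster_rows, test_rows, model_rows = [], [], []
    for si, name in enumerate(TRAIT_SETS):
        X = feats[name]
        res = morph.kmeans_morphospace(
            X, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            n_init=cfg.n_init, seed=cfg.stage_seed(20 + si),
        )
        for sp, cl in res.assignment.items():
            cluster_rows.append((name, sp, cl, res.chosen_k))
        for pred_name, pred in (("habitat", hx), ("relatedness", cov)):
            try:
                t = morph.cluster_association(res.assignment, pred)
                test_rows.append(
                    (name, pred_name, t["method"], t["statistic"], t["F"],
                     t["df1"], t["df2"], t["p"])
                )
            except ValueError:
                test_rows.append((name, pred_name, "na", np.nan, np.nan,
                                  np.nan, np.nan, np.nan))
        # PGLS model set
        m_hab = morph.PGLS(X, hx, corr=None).fit()
        m_rel = morph.PGLS(X, None, corr=cov).fit()
        m_both = morph.PGLS(X, hx, corr=cov).fit()
        for label, m in (("habitat", m_hab), ("relatedness", m_rel), ("both", m_both)):
            model_rows.append(
                (name, label, m.loglik, m.n_params, m.adj_r2, np.nan, np.nan, np.nan)
            )
        for label, reduced in (("relatedness", m_rel), ("habitat", m_hab)):
            lrt = morph.lrt_compare(m_both, reduced)
            model_rows.append(
                (name, f"both_vs_{label}", m_both.loglik, m_both.n_params,
                 m_both.adj_r2, lrt.statistic, lrt.df, lrt.p)
            )
    pd.DataFrame(
        cluster_rows, columns=["trait_set", "species", "cluster", "chosen_k"]
    ).to_csv(out / "clusters.csv", index=False)
    pd.DataFrame(
        test_rows,
        columns=["trait_set", "predictors", "method", "statistic", "F",
                 "df1", "df2", "p"],
    ).to_csv(out / "cluster_tests.csv", index=False)
    pd.DataFrame(
        model_rows,
        columns=["trait_set", "model", "loglik", "n_params", "adj_r2",
                 "lrt_stat", "lrt_df", "lrt_p"],
    ).to_csv(out / "models.csv", index=False)
    _stage_done(out, "morphospace", key)
    log.info("morphospace: wrote %s", files)
    return files


def stage_rates(cfg: RunConfig, out: Path) -> list[str]:
    files = ["branch_rates.csv", "shifts.csv", "tree_nodes.nwk"]
    key = cfg.config_hash + ":rates:" + _file_hash(out / "traits.csv")
    if _stage_fresh(out, "rates", key, files):
        log.info("rates: cached")
        return files
    tree = treeio.read_newick_file(out / "tree.nwk")
    feats = _load_feature_sets(out)
    habitat = pd.read_csv(out / "habitat.csv").set_index("species")
    rate_frames, shift_rows = [], []
    for si, name in enumerate(TRAIT_SETS):
        X = feats[name].loc[tree.taxa]
        res = rates_mod.PhylogeneticRidge(tree, X).fit()
        rf = res.rates_frame()
        rf.insert(0, "trait_set", name)
        rate_frames.append(rf)
        for sh in res.search_shift_clade(
            min_clade=cfg.min_clade, n_rand=cfg.n_rand,
            seed=cfg.stage_seed(30 + si),
        ):
            shift_rows.append(
                (name, "clade", sh.unit, sh.n_branches, sh.rate_delta,
                 sh.p_raw, sh.p_adjusted, sh.direction)
            )
        for th in cfg.thresholds:
            states = {
                s: conv.classify_habitat(t, th)
                for s, t in habitat["mean_temp"].items()
            }
            try:
                for sh in res.search_shift_state(
                    states, n_rand=cfg.n_rand, seed=cfg.stage_seed(40 + si)
                ):
                    shift_rows.append(
                        (name, f"state_{th:g}C", sh.unit, sh.n_branches,
                         sh.rate_delta, sh.p_raw, sh.p_adjusted, sh.direction)
                    )
            except ValueError as exc:
                log.warning("state shift test skipped (%s)", exc)
    pd.concat(rate_frames).to_csv(out / "branch_rates.csv", index=False)
    pd.DataFrame(
        shift_rows,
        columns=["trait_set", "test", "unit", "n_branches", "rate_delta",
                 "p_raw", "p_adjusted", "direction"],
    ).to_csv(out / "shifts.csv", index=False)
    # newick with node ids as internal labels, for locating flagged nodes
    labeled = treeio.PhyloTree(
        tree.parent, tree.brlen, tree.labels,
        tuple(float(i) if tree.labels[i] is None else None
              for i in range(tree.n_nodes)),
    )
    (out / "tree_nodes.nwk").write_text(treeio.write_newick(labeled) + "\n")
    _stage_done(out, "rates", key)
    log.info("rates: wrote %s", files)
    return files


def stage_convergence(cfg: RunConfig, out: Path) -> list[str]:
    files = ["convergence.csv"]
    key = cfg.config_hash + ":convergence:" + _file_hash(out / "traits.csv")
    if _stage_fresh(out, "convergence", key, files):
        log.info("convergence: cached")
        return files
    tree = treeio.read_newick_file(out / "tree.nwk")
    feats = _load_feature_sets(out)
    habitat = pd.read_csv(out / "habitat.csv").set_index("species")
    rows = []
    run = 0
    for th in cfg.thresholds:
        states = pd.Series(
            {s: conv.classify_habitat(t, th) for s, t in habitat["mean_temp"].items()}
        )
        for state in ("riparian", "alpine"):
            for name in TRAIT_SETS:
                run += 1
                try:
                    ana = conv.ConvergenceAnalysis(
                        tree, feats[name].loc[tree.taxa], states, state
                    )
                    r = ana.fit(
                        n_sim=cfg.n_sim, n_perm=cfg.n_perm,
                        seed=cfg.stage_seed(50 + run),
                    )
                except ValueError as exc:
                    log.warning("convergence %s/%s/%sC skipped (%s)",
                                name, state, th, exc)
                    continue
                row = r.to_frame().iloc[0].to_dict()
                row.update(trait_set=name, threshold=th, n_focal=len(ana.focal))
                rows.append(row)
    cols = ["trait_set", "state", "threshold", "n_focal",
            "C1", "p1", "C2", "p2", "C3", "p3", "C4", "p4",
            "theta_deg", "theta_rad", "theta_per_time_deg",
            "p_theta", "p_theta_time"]
    pd.DataFrame(rows)[cols].to_csv(out / "convergence.csv", index=False)
    _stage_done(out, "convergence", key)
    log.info("convergence: wrote %s", files)
    return files


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in dependency order; returns the file manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        manifest = {
            "data": stage_data(cfg, out),
            "efa": stage_efa(cfg, out),
            "morphospace": stage_morphospace(cfg, out),
            "rates": stage_rates(cfg, out),
            "convergence": stage_convergence(cfg, out),
        }
    finally:
        log.removeHandler(fh)
        fh.close()
    tables = {
        name: pd.read_csv(out / f)
        for name, f in [
            ("clusters", "clusters.csv"),
            ("models", "models.csv"),
            ("shifts", "shifts.csv"),
            ("convergence", "convergence.csv"),
        ]
    }
    report = RunReport(
        outdir=str(out), config_hash=cfg.config_hash,
        manifest=manifest, tables=tables,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    return report
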