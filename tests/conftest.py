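import numpy as np
import pytest

import convmorph as cm


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); -- the standard analytic fixture."""
    return cm.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule20():
    return cm.simulate_yule_tree(20, 1.0, seed=3)


@pytest.fixture(scope="session")
def yule16():
    return cm.simulate_yule_tree(16, 1.0, seed=31)


def circle_outline(n=256, r=1.0, phase=0.0):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + phase
    return cm.Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def blob_outline(n=256, seed=0):
    """Smooth star-convex blob with a decaying perturbation spectrum."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.ones(n)
    for k in range(2, 8):
        amp = 0.4 / k**2
        r += amp * (rng.uniform(-1, 1) * np.cos(k * th) + rng.uniform(-1, 1) * np.sin(k * th))
    return cm.Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def strong_convergence_config(tree, minf=6):
    """Balanced two-regime OU scenario with widely separated optima."""
    h = tree.height()
    sig = np.array([0.02, 1.0, 0.04, 0.04])
    root = np.array([0.8, 6.0, 1.8, 1.5])
    sep = 14.0 * np.sqrt(sig * h)
    return cm.SimConfig(
        n_species=tree.n_tips,
        regime_pull=20.0 / h,
        temp_sigma2=60.0,
        temp_root=6.0,
        optima={
            "alpine": tuple(root + sep / 2),
            "riparian": tuple(root - sep / 2),
        },
    )
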