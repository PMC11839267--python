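# convmorph

Phylogenetic comparative analysis of **ecomorphological convergence**, built
for the kind of question posed by montane ground-beetle assemblages
(*Nebria*): when distantly related species specialize on the same habitat —
alpine snowfields above the tree line versus riparian stream margins below
it — do their functional traits (body size, elytral and pronotal
proportions, outline shape) converge on habitat-specific morphotypes, or is
morphological similarity explained by shared ancestry?

The package implements the full analysis chain as reusable, tested library
code, together with a synthetic-data generator that reproduces the
statistical structure the analysis assumes, so every stage can be validated
against known ground truth.

## What it computes

* **Outline shape features** — elliptical Fourier analysis (EFA) of closed
  2-D outlines (Kuhl–Giardina closed-contour formulas, chord-length
  parameterization), normalization invariant to rotation, scale,
  translation and starting point, and PCA shape scores.
* **Tree structure** — Newick I/O, support-based node collapsing, pruning,
  patristic distances, and the Brownian-motion (BM) covariance
  `C[i,j] = depth of MRCA(i,j)` with its relatedness correlation matrix.
* **Branch-wise evolutionary rates** — phylogenetic ridge regression: tip
  values regressed on root-to-tip branch-length paths, penalty chosen by
  GCV; per-branch coefficients are rates of change and their partial sums
  give ancestral states.  Rate *shifts* (clade-wise and habitat-state-wise)
  are detected with a parametric-bootstrap null and Bonferroni control.
* **Convergence metrics** — Stayton's C1–C4.  For a focal pair, `Dtip` is
  the current phenotypic distance and `Dmax` the largest distance between
  the two lineages' reconstructed states since their MRCA:

      C1 = 1 − Dtip / Dmax          C2 = Dmax − Dtip
      C3 = C2 / L_tot.lineage       C4 = C2 / L_tot.clade

  with significance from BM re-simulation.  A complementary angular test
  measures the mean angle θ between same-habitat species' displacement
  vectors from the root state (and θ per unit patristic time), with
  permutation significance.
* **Morphospace structure** — k-means clustering with an elbow rule on the
  within-group sum of squares, MANOVA/ANOVA + Tukey HSD of clusters against
  habitat variables and relatedness, collinearity screening at |r| < 0.75,
  and phylogenetic GLS regression (habitat, relatedness, or both) compared
  by likelihood-ratio tests.
* **Synthetic data** — Yule trees, a Brownian thermal variable thresholded
  at 6 or 7 °C into alpine/riparian regimes, traits evolving by BM or by
  exact Ornstein–Uhlenbeck transitions toward regime-specific optima,
  specimen-level noise, and superellipse beetle outlines whose axis ratio
  and angularity covary with the traits.

## Worked example

```python
import convmorph as cm

tree = cm.simulate_yule_tree(40, birth_rate=1.0, seed=7)
cfg = cm.SimConfig(n_species=40, seed=7)
truth = cm.simulate_convergent(tree, cfg)      # traits + habitat states

res = cm.ConvergenceAnalysis(
    tree, truth.species_means, truth.habitat, "alpine"
).fit(n_sim=500, n_perm=500, seed=1)
print(res.summary())
```

which prints (seed-exact):

```
Convergence of state 'alpine' (22 species)
  C1 = 0.1943 (p = 0.3633)   C2 = 0.2123 (p = 0.7246)
  C3 = 0.1066 (p = 0.3932)   C4 = 0.009588 (p = 0.7305)
  theta = 84.44 deg (1.474 rad), p = 0.01198
  theta/time = 23.35 deg/time, p = 0.3992
```

Here 22 of the 40 simulated species are alpine; C1 ≈ 0.19 says the average
alpine pair has closed about a fifth of the maximum phenotypic distance its
two lineages ever reached, which is not distinguishable from the Brownian
null (p ≈ 0.36), while the mean angle between alpine displacement vectors
(84° ≈ 1.47 rad) *is* smaller than random same-size species sets
(p ≈ 0.012) — the generator's default regime attraction is mild, so the
distance-ratio metrics stay null while the directional test already picks
up the shared pull.

Branch-rate shifts on the same data:

```python
rates = cm.PhylogeneticRidge(tree, truth.species_means).fit()
shifts = rates.search_shift_clade(n_rand=1000, seed=1)
print(rates.summary())
print([s for s in shifts if s.p_adjusted < 0.05])
```

The whole chain (simulate → EFA → morphospace → rates → convergence) runs
from one YAML config:

```sh
convmorph run --config run.yaml
```

with per-stage caching and byte-identical outputs under a fixed seed.

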