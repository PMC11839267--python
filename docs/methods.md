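# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `convmorph`.  It is the design record a maintainer should
read before changing defaults.

## The scientific setting

A clade of habitat-specialist species (the motivating system is montane
ground beetles split between *alpine* and *riparian* habitats by the tree
line) is observed at the tips of a dated phylogeny, with specimen-level
linear measurements (antennal scape length, elytral length, elytral ratio,
pronotal ratio) and closed 2-D outlines of two structures (pronotum,
elytron).  Habitat state is defined by thresholding mean annual ground
temperature at 6 °C (alternatively 7 °C): alpine iff the temperature is at
or below the threshold, the treeline criterion.  Three questions are asked:
how fast do the traits evolve and where do rates shift; whether habitat or
relatedness predicts trait variation; and whether same-habitat species have
converged.

## Outline shape: elliptical Fourier analysis

Closed outlines are decomposed with the Kuhl–Giardina closed-contour
formulas under a **piecewise-linear, cumulative-chord-length
parameterization** — inputs are coordinate lists, not rasters, so no chain
code is involved.  Per harmonic n the four coefficients (a_n, b_n, c_n,
d_n) describe an ellipse; harmonic power is (a²+b²+c²+d²)/2.

Normalization makes coefficients invariant to translation (drop A0/C0),
rotation and starting point (first-harmonic phase/orientation rotations),
and scale (semi-major axis of the first harmonic = 1).  The residual
four-fold ambiguity (major/minor axis, two endpoints) is resolved by
taking the candidate with the largest first-harmonic amplitude and, among
ties, the lexicographically largest coefficient vector — a deterministic
canonical form verified invariant to 1e-8 under random similarity
transforms.  **Reflection is deliberately not normalized away**: sidedness
is biological, and left/right structures must be consistently oriented
upstream.

A consequence of chord-length parameterization worth knowing: the first
harmonic of a non-circular ellipse is not exactly that ellipse (the
chord-length phase is not the trigonometric phase), so the first-harmonic
"area" a1·d1 − b1·c1 of a 2:1 ellipse converges to ≈ 1.96, not 2.0.  Tests
assert the converged behavior.

Harmonic count defaults to the smallest N reaching 99 % mean cumulative
power (configurable); a threshold of exactly 1.0 returns the Nyquist
maximum.  Downstream analyses use normalized coefficients averaged within
species, then PCA scores keeping 95 % variance — both the coefficients and
the scores are exposed.

## Trees and the Brownian covariance

`PhyloTree` is a parent-pointer array structure (preorder ids, root branch
length 0).  Newick parsing/writing goes through dendropy; supports are read
from internal node labels, and nodes with support below 90 % (configurable)
collapse into polytomies with child branch lengths incremented, preserving
all root-to-tip depths exactly.  Missing supports are treated as fully
supported — only nodes known to be weak are collapsed.  Pruning keeps
patristic distances exact and retains a unary root (it anchors depth).

Under Brownian motion, `C[i,j]` = depth of MRCA(i,j).  The correlation
matrix used in regressions is C divided by tree height for ultrametric
trees and `C_ij/√(C_ii C_jj)` otherwise (the normalization is a package
choice; both agree on ultrametric trees).

## Phylogenetic ridge regression

Tip values y are modeled as root + L β, where L is the tips × branches
path matrix (`L[i,b]` = length of branch b if it lies on tip i's root
path).  β is the per-branch rate of change; ancestral states are root plus
the accumulated brlen·β along root-to-node paths.  The root is an
unpenalized intercept; β carries an L2 penalty λ chosen by GCV on a
30-point log grid spanning [1e-6, 1e3] × tr(LLᵀ)/n.  Using the
push-through identity, with M = LLᵀ:

    root = 1ᵀ(M+λI)⁻¹y / 1ᵀ(M+λI)⁻¹1,   β = Lᵀ(M+λI)⁻¹(y − root·1)

which is well-defined at λ = 0 as the minimum-norm interpolant — the limit
of the ridge path.  On a star tree this reduces to root = ȳ and
β_i = (y_i − ȳ)/l_i exactly.  Multivariate traits are fitted per dimension
(own λ each); the per-branch *rate* is the Euclidean norm of the
coefficient vector across dimensions.

Ancestral states from this path model differ from Felsenstein GLS
reconstruction (the implicit weighting is by squared, not linear, branch
lengths); across BM simulations the RMS difference is ~10 % of the tip
standard deviation (max ~19 % per dataset).  Tips are reproduced exactly
at λ = 0.

### Rate shifts

For each internal node (clade = its branch plus all descendant branches;
minimum clade size 1 branch) or each habitat state, the statistic is the
difference in mean **standardized** absolute rates inside vs. outside.
Standardization divides each branch's coefficient by its analytic null
standard deviation under unit-rate BM (sd_b = √diag(ACAᵀ) for the linear
estimator β = Ay), because terminal and deep branches otherwise differ
strongly in sampling variance.

The null distribution is a **parametric bootstrap**: BM is re-simulated
with the GLS-estimated per-trait rate, and every replicate passes through
the identical pipeline (GCV selection, ridge fit, standardization) before
the per-node statistics are recomputed; p is the two-tailed exceedance
against the null statistics centered at their null mean, with the
small-sample correction (1+k)/(1+n), Bonferroni-adjusted over tested nodes
(per trait-set family).  A plain permutation of rates across branches is
retained as `method="permutation"` but is anti-conservative: branch-rate
estimates are correlated by construction, violating exchangeability
(measured familywise error ~0.10–0.14 vs. 0.02 for the bootstrap at
nominal 0.05).  With ~50 tested clades, n_rand must exceed m/α for the
p-value floor to clear Bonferroni; power analyses use n_rand = 2000.

For the state ("sparse") test, a branch carries a state iff all its
descendant tips share it; mixed branches are excluded from the comparison
entirely, which makes the two-state statistics exactly antisymmetric and
avoids circular ancestral-state inference.  Reported deltas are signed,
with an explicit slower/faster direction field.

## Convergence metrics

**Stayton C1–C4.**  For each focal pair, Dtip is the Euclidean distance
between tip feature vectors; Dmax is the maximum distance between any two
reconstructed states on the two lineages from the MRCA to the tips
(MRCA and tips included, so Dmax ≥ Dtip and C1 ∈ [0,1]).
C2 = Dmax − Dtip; C3 divides C2 by the summed per-branch Euclidean change
along both lineages; C4 divides by the same sum over every branch of the
smallest clade containing *all* focal taxa.  Pair values are averaged
(per-pair tables are also emitted).  Pairs with Dmax = 0 are dropped with
a warning.  Significance: multivariate BM is re-simulated with the
evolutionary rate matrix estimated by GLS from the data
(R̂ = (X−μ̂)ᵀC⁻¹(X−μ̂)/(n−1), the independent-contrasts covariance), the
metrics recomputed for the same focal set, and p = (1+#{sim ≥ obs})/(1+n).
Measured type-I error of the C1 test at α = 0.05 is ≈ 0.05.

**Angles.**  Feature vectors are centered at the reconstructed root state
(so angles measure the *direction* of net evolutionary displacement;
centering at the grand mean is available).  θ is the mean pairwise
arc-cosine angle among focal species, reported in degrees and radians;
θ/time divides each pair's angle by its patristic distance.  One-tailed
permutation significance draws random species subsets of the focal size;
small observed angles are evidence of convergence.  When the focal set is
all species, p = 1 by construction.  A structural note: under strong
two-regime convergence, permutation subsets drawn entirely from one regime
also have small angles, which caps attainable power around 0.85–0.9 for
small minority focal sets; power analyses therefore use balanced regimes.

## Morphospace statistics

k-means (scikit-learn, best of n_init restarts, seeded) scans k = 1..10;
the elbow is the maximum second difference of the within-group sum of
squares.  Cluster labels are re-indexed contiguously.  Cluster association
uses a one-way MANOVA (Wilks' Λ with Rao's F approximation, reducing to
the ANOVA F — and to the squared two-sample t — for one variable and two
groups), with Pillai's trace as the fallback when the within-group SSCP is
singular, plus Tukey HSD contrasts per variable.  Relatedness enters as
the leading principal coordinates of the correlation matrix (95 %
variance).  Habitat variables pass a greedy collinearity screen in column
order at |Pearson r| < 0.75, with latitude and elevation forced to the
front of the order because they always enter the habitat regressions as
fixed effects.

Regression compares three models per feature set — habitat fixed effects
(OLS), relatedness only (GLS with the BM correlation), and both — fitted
by maximum likelihood; multivariate responses are fitted per feature with
a shared design and summed log-likelihoods (a response "correlation
matrix" is not a standard estimable quantity; this per-feature GLS is the
documented substitute).  Likelihood-ratio tests use 2Δℓ (clipped at 0)
against χ² with df = the difference in parameter counts (coefficients plus
one variance per feature).  The null LRT statistic for one extra noise
predictor has mean ≈ 1 over replicates, as it should.  Sexes are pooled
after a provided per-trait two-sample t-test (sex differences, when
simulated, are small relative to between-species variation).

## The synthetic-data generator

The generator's defaults are the study conditions: 79 species, 17
specimens per species, four linear traits with root state
(0.8 mm scape, 6.0 mm elytral length, 1.8 elytral ratio, 1.5 pronotal
ratio), BM rates (0.02, 1.0, 0.04, 0.04) per unit tree height,
within-species measurement sd (0.05, 0.30, 0.05, 0.05), a Yule tree with
birth rate 1, and a thermal variable starting at 5.5 °C with rate
4 °C²/time thresholded at 6 °C — giving a slight alpine majority, as in
the real assemblage.  Habitat-specific optima default to larger/rounder
alpine and smaller/more-angular riparian morphotypes with a moderate OU
attraction (α = 1).

Regimes switch along branches: each branch is divided into segments (at
most height/50 long), the thermal variable takes a BM step per segment,
and the segment's regime is alpine iff its midpoint temperature is at or
below the threshold; traits then follow the **exact OU transition** per
segment (α = 0 reduces algebraically to BM — no Euler discretization
anywhere).  This yields phylogenetically clustered but occasionally
convergent habitat states, and the tip's recent regime agrees with its
labeled state except for lineages that cross the threshold at the very
end.  Those boundary-hovering lineages are a real feature of
threshold-defined habitats: they sit between optima, so even under very
strong attraction a per-replicate "perfect recovery" criterion is
unattainable, and recovery statements are made on averages.

Outlines are superellipses |x/a|^m + |y|^m = 1 with a = the structure's
length:width ratio and m = 2 + angularity, where angularity is a
non-negative weighted combination of trait deviations from the root state
(weights per structure in the config); angularity 0 gives an exact
ellipse and increasing angularity moves power into harmonic 3.
Specimen sexes alternate; specimen noise is i.i.d. normal.

Everything is a pure function of (config, seed); the pipeline expands one
master seed into per-stage seeds by a fixed affine rule modulo 2³¹.

## What the synthetic data do and do not show

The generator reproduces the assumed statistical structure: BM/OU trait
evolution on a known tree, threshold-defined habitat states correlated
with phylogeny, measurement noise, and trait-linked outline shape.  It
does not emulate allometric scaling, sexual dimorphism beyond a constant
shift, biogeography, intraspecific phylogeography, variable specimen
counts (fixed n per species by default), or real silhouette digitization
noise.  Passing tests therefore demonstrate the *estimators'* correctness
and calibration under the assumed model, not robustness to model
violations in real data.

## Problem sizes used in the test and acceptance runs

Calibration tests use 16–20-tip trees (500 replicates for familywise
error and permutation-null uniformity, 300 for the Stayton type-I band,
100 for power), a 50-tip tree for the 10× rate-clade power check, and the
full 79-species pipeline (n_sim = 200–500, n_perm = 500–1000,
n_rand = 500–1000) for end-to-end determinism and the reported headline
quantities.  These sizes make the whole suite run in a few minutes while
leaving the binomial error of each calibration check well inside its
asserted band.

## Known limitations

* The ridge path model's ancestral states are not the GLS/ML states; they
  are internally consistent with the rate estimates (as in ridge-based
  rate analysis generally) but should not be quoted as ML reconstructions.
* GCV occasionally selects a very small λ on small trees, making rates
  near-interpolating; the standardization absorbs most of the resulting
  variance heterogeneity.
* The angle test's permutation null compares against arbitrary species
  sets, not phylogenetically structured ones; with very strong phylogenetic
  clustering of the focal state this is mildly conservative.
* C2 (and C4's numerator) are scale-dependent (trait units); compare them
  only within a feature set.
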