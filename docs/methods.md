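# Methods

This note records the models, conventions and numerical choices behind
`sgmnet`, in the spirit of a statistical software methods appendix. The
package implements a single-subject gray matter network analysis (cube
nodes, maximum rotated similarity, FDR-thresholded edges, normalized
small-world metrics), a cross-validated brain-age model, and the age/sex
statistics of an aging-cohort workup, driven by a synthetic-cohort
generator.

## Network construction

**Nodes.** The volume is tiled by non-overlapping 3×3×3-voxel cubes
anchored at the grid origin; a cube becomes a node when the fraction of its
27 voxels that are inside the brain mask *and* positive reaches the
inclusion threshold (default 1.0 — all 27; configurable, since no standard
rule exists). Node order is lexicographic in grid index, making all outputs
bit-reproducible.

**Maximum rotated similarity.** The similarity of two nodes is the maximum
Pearson correlation over the 48 exact symmetries of the cube lattice (all
axis permutations × axis sign flips, represented as permutations of the 27
positions; the group is closed under composition and inversion, so the
score is symmetric in its arguments). Rotations by odd multiples of 45°
cannot be represented exactly on a 3×3×3 lattice; a trilinear-interpolation
dialect (`dialect="interp45"`) augments the lattice set with resampled
45°-rotation operators about each axis. It is approximate (resampling is
not orthogonal), strictly increases the similarity, and is off by default.
Zero-variance cubes have undefined correlation; their similarity is defined
as 0 and the node is flagged.

**Edge significance.** Two routes are implemented.

* `fdr_binarize` — the textbook route: each correlation r is converted to a
  one-sided p-value via t = r·√(df/(1−r²)) with df = 25 (27 values − 2) and
  Benjamini–Hochberg control is applied at q over all pairs. This is the
  correct procedure for plain correlations and is verified against a
  step-by-step BH oracle. It is **not** appropriate for max-rotated
  similarities: maximizing over 48 transforms shifts the null to r ≈ 0.4
  (p ≈ 0.01), so BH rejects nearly every pair and the graph saturates for
  any input.
* `permutation_null_binarize` (pipeline default) — the null is estimated
  empirically: each cube's 27 values are randomly permuted (destroying
  spatial correspondence while preserving value distributions), the
  max-rotated similarity is recomputed for all permuted pairs, and observed
  similarities get one-sided empirical p-values against this pooled null
  before BH at q = 0.05. This realizes the design goal that the cutoff
  bounds the rate of spurious connections, and produces sparse
  (density ~0.05–0.25) networks.

Because the empirical p-value is monotone in r, both routes reduce to a
single scalar correlation cutoff per matrix (reported as `r_threshold`).
For cohort runs, `cohort_properties` pools all subjects' observed and null
similarities into **one** BH threshold applied to everyone (the "one
threshold for all participants" convention). Pooling removes per-subject
BH-threshold jitter — measured at 30³ voxels it cuts the between-subject γ
standard deviation from ≈0.7 to ≈0.45 — and makes subjects directly
comparable; per-subject FDR remains available (`null_method="permutation"`).

## Small-world metrics

Per-node clustering is C_i = 2t_i/(k_i(k_i−1)) with t_i the edges among
node i's neighbors (computed as ((A·A)∘A)1/2); nodes with degree < 2
contribute C_i = 0 and stay in the mean — the convention of averaging over
all nodes. Characteristic path length is the mean breadth-first shortest
path over ordered pairs within the largest connected component (a warning
fires when that component holds <90% of nodes; a harmonic/efficiency-style
variant is available for fragmented graphs). Normalization divides by the
mean of 5 degree-preserving randomized references: γ = C/C_rand,
λ = L/L_rand, σ = γ/λ (exactly, by construction).

Randomization is Maslov–Sneppen double-edge swapping: 10 swap attempts per
edge, uniform edge sampling with random orientation, rejecting self-loops
and multi-edges. The inner loop is a numba-compiled kernel (with a
vectorized numpy fallback) seeded deterministically; near-complete graphs
(density > 0.9) are returned unchanged with a warning since they admit
essentially no swaps. Degree sequences are preserved exactly; on ring
lattices clustering collapses (0.5 → ≈0.01) and on Erdős–Rényi inputs
γ, λ, σ all return to 1 within ±0.1 — the self-consistency checks in the
test suite.

## Brain age

`BrainAgeModel` regresses chronological age on voxel intensities inside
the intersection brain mask: PCA reduction (100 components at full scale;
capped at the training rank with a warning at desk scale) followed by
linear ν-SVR (C = 1, ν = 0.5; ε-SVR optional). K-fold cross-validation
(default 10) refits **both** the PCA basis and the regression inside each
training split, so held-out subjects never influence the basis
(`basis="global"` reproduces pipelines that reduce once on all data).
Features enter unstandardized by default — voxel intensities share units —
with z-scoring behind a flag. `BrainAgeResults` carries pooled held-out
predictions, MAE, RMSE, r, per-subject brain-PAD (predicted − chronological
age), and a `summary()` table.

## Statistics

* **Mann–Whitney U**: full enumeration of group assignments (midranks for
  ties) when the combined n ≤ 12, tie-corrected normal approximation
  otherwise. Network properties are judged at the Bonferroni level
  0.05/3, demographics at 0.05.
* **Age×sex interaction model** (per stratum, split at 70 years; age 70.0
  belongs to the upper stratum): OLS fit of
  `response ~ age + female + age:female + n_nodes + scanner`.
  Standardized coefficients refit the model with every design column and
  the response z-scored; the interaction column is z-scored *as formed*,
  so under the strong age-by-dummy collinearity of a narrow stratum
  standardized coefficients can exceed 1 — reproduced deliberately, as
  reported analyses of this design show the same behavior. If the
  interaction p ≥ 0.05 the age and sex main effects are re-estimated
  without the interaction term and reported alongside.
* **ANCOVA sex contrast**: `response ~ female + age + n_nodes + scanner`;
  adjusted means per sex are evaluated at the stratum's covariate means
  with standard errors from the coefficient covariance.
* **Partial correlation**: residualize both variables on the covariates
  (with intercept) via least squares, correlate residuals, test on
  n − 2 − k df. With no covariates this is exactly Pearson. Verified to
  1e-10 against the precision-matrix identity and against `pingouin`.
* **Dependent overlapping correlations** (property × chronological age vs
  property × brain age): Fisher-z statistic with the backtransformed
  average correlation in the variance term (Hittner-style; Steiger's
  average-r variant behind a flag). Monte-Carlo calibration over 10⁴
  trivariate-normal null replicates keeps the type-I error within
  [0.035, 0.065] at nominal 0.05.
* **Age trajectories**: Gaussian GAM per sex — B-spline basis in age
  (df 6, cubic) plus linear node-count and scanner terms; the smoothing
  penalty is selected by 5-fold cross-validation over a log grid (the
  installed statsmodels' built-in penalty selection is broken). Curves are
  evaluated at group covariate means on the age range common to the groups,
  with pointwise standard errors from the penalized covariance.

`run_full_analysis` emits four tables — sex comparison of demographics and
properties; interaction models per stratum; adjusted sex contrasts;
partial correlations with the dependent-correlation comparison — plus a
JSON manifest recording alphas, model formulas, the 70-year split and
seeds.

## Synthetic cohorts

The generator provides the *statistical* structure the analysis assumes,
not anatomical realism. Each volume is built from

* a **pattern-mixture field**: 32 high-frequency 3×3×3 template patterns
  blended cube-by-cube with per-template weight fields. Weights mix a
  spatially smooth component (Gaussian scale 1.5 cubes — neighboring cubes
  share morphology, chance alignments create long-range similarity) with a
  subject-wide **common morphology vector**. The mixing proportion is the
  subject's `covariance_strength` c (plus a smooth per-cube jitter of 0.15
  that spreads the transition): c → 1 means fully differentiated local
  morphology (sparse, clustered, small-world graphs); lower c raises a
  non-specific similarity floor between all cubes, densifying and
  randomizing the graph — the de-differentiation model of network aging.
  In consequence γ falls monotonically from ≈2.4 (c ≥ 0.5) to ≈1.6
  (c = 0.3) at the default 30³ scale, with λ declining in parallel;
* a fixed 25% i.i.d. voxel-noise fraction (set `detail_fraction=1.0` for a
  pure-noise volume);
* an ellipsoidal brain mask whose scale carries head-size effects, and a
  mean intensity declining with age (atrophy).

Cohort structure: ages uniform over the requested range (the emulated
cohort's age distribution is even across decades), exact sex counts,
alternating scanner labels, and per-subject covariance strength

```
c = 0.535 − 0.0029·age + 0.08·[female]
    − 0.011·max(0, age − 70)·[female] + N(0, 0.02)
```

clipped to [0, 1] with a warning. The defaults place the cohort on the
responsive part of the γ(c) curve and encode: γ declining with age; women
above men before 70; and an extra female decline past 70 sized so the
covariate-adjusted sex gap closes (averages ≈0 over ages 70–85) rather
than reversing — the qualitative pattern the analysis stage must recover.
Atrophy enters twice: mean intensity falls 0.6%/year (this is what the
brain-age model reads; at the default it carries enough variance to rank
among the leading principal components) and the mask scale shrinks
0.06%/year, with men's masks 2% larger — so node counts fall with age and
are higher in men.

Desk-scale geometry: 30³ voxels at 6 mm (≈300–380 nodes) by default. The
coarse voxel keeps the i.i.d. detail alive through the 8-mm smoothing
(σ ≈ 0.57 voxel); at finer grids every cube becomes a smooth gradient,
rotation alignment makes all pairs correlate, and similarity graphs
saturate. Real cohorts (~1.5 mm voxels, ~7000 nodes) live in a different
regime, so absolute γ/λ/σ magnitudes here are not comparable to published
cohort values; directions, orderings and the small-world classification
are.

**What passing tests do and do not show.** The synthetic fields have no
cortical geometry, no tissue classes, no scanner physics (the scanner label
is purely categorical), and their similarity structure is stationary apart
from the injected effects. Tests therefore validate the *procedures* —
construction, metrics, models, inference — and the recoverability of known
effect structure, not anatomical claims about real brains.

## Numerical conventions

* FWHM/σ conversion: σ = FWHM/(2√(2 ln 2)); smoothing uses reflective
  boundaries (conserves total intensity exactly); a renormalized
  zero-padded mode is available.
* All randomness flows through explicit integer seeds; one master seed
  fans out to stages via `numpy.random.SeedSequence`, so cohort results do
  not depend on subject processing order and CLI re-runs are byte-identical.
* Similarity matrices are clipped to [−1, 1] and symmetrized by taking the
  elementwise maximum with their transpose (guarding against
  summation-order noise of ~1e-16).
* Empirical p-values use add-one smoothing: p = 1 − rank/(N_null + 1).
* Degenerate inputs: edgeless graphs raise for path length; zero-variance
  references raise; constant ages or predictions flag the correlation as
  undefined; constant responses short-circuit the GAM to a flat curve.

## Known limitations

* The γ(c) response saturates for c ≥ 0.5 and compresses at small volumes
  (≤21³), so effect-recovery studies need the 30³ default.
* Between-subject γ variability (sd ≈ 0.45 under pooled thresholding) is
  several times the real cohort's, limiting per-cohort power for the
  stratified interaction/ANCOVA analyses at desk scale; the replicate-cohort
  tests therefore compare detection counts across 20 cohorts.
* The interpolated 45° dialect is a non-orthogonal approximation and is
  provided for comparison only.
* Brain-PAD bias correction (regression-to-the-mean adjustment) is out of
  scope.
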