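# sgmnet — single-subject gray matter networks, small-world metrics, brain age

`sgmnet` implements an end-to-end analysis of age- and sex-related change in
**single-subject similarity-based gray matter networks**, the kind of
network built from one person's structural MRI alone. It is aimed at
neuroimaging methods researchers who want a tested, reproducible
implementation of the whole chain — network construction, small-world
quantification, brain-age prediction, and the cohort statistics — together
with a synthetic-cohort generator so every stage can be exercised and
validated without access to clinical MRI data.

## The method

Starting from a preprocessed (segmented, spatially normalized, smoothed)
gray matter volume:

1. **Nodes** are non-overlapping 3×3×3-voxel cubes; each node's feature
   vector is its 27 intensities.
2. **Similarity** between two nodes is the *maximum rotated correlation*:
   the largest Pearson correlation over the 48 rotations/reflections of the
   cube lattice, which makes the score insensitive to local differences in
   folding orientation. (An interpolated 45° dialect is available.)
3. **Edges** are pairs whose similarity is statistically significant under
   Benjamini–Hochberg FDR control at q = 0.05. Because maximizing over 48
   transforms inflates the null, significance is calibrated against an
   empirical permutation null by default (each cube's values shuffled, all
   pair similarities recomputed).
4. **Small-world properties** compare the binary graph with five
   degree-preserving (Maslov–Sneppen) randomized references:

   γ = C / C_rand  (normalized clustering)
   λ = L / L_rand  (normalized path length)
   σ = γ / λ    (small-world coefficient)

   where C is the mean clustering coefficient and L the characteristic
   path length. A network is small-world when γ > 1, λ ≈ 1, σ > 1.
5. **Brain age** is predicted from in-mask voxel intensities by PCA (100
   components at full scale) followed by linear ν-SVR (C = 1, ν = 0.5),
   evaluated with 10-fold cross-validation; brain-PAD = predicted −
   chronological age.
6. **Statistics**: Mann–Whitney sex comparisons (Bonferroni α = 0.05/3 for
   the three network properties), age×sex interaction models and
   ANCOVA-style adjusted sex contrasts in the <70 / ≥70 year strata
   (controlling node count and scanner), GAM age-trajectory curves, and
   partial correlations of each property with chronological vs predicted
   age (α = 0.05/2) compared by a Fisher-z test for dependent overlapping
   correlations.

The synthetic-cohort generator emulates the statistical structure this
analysis needs: gray-matter-like fields whose cube-level covariance is
locally coherent in the young brain and progressively de-differentiates
with age (an increasing non-specific similarity floor that densifies and
randomizes the network, lowering γ), with higher network properties in
women, an extra female decline past age 70, global atrophy, and larger male
brain masks.

## Worked example

```python
import numpy as np
from sgmnet import (CohortSpec, generate_cohort, cohort_properties,
                    BrainAgeModel, vectorize_volumes, gaussian_smooth)
from sgmnet.stats import run_full_analysis

spec = CohortSpec(n_subjects=60, age_range=(40.0, 85.0), seed=42)
records, volumes = generate_cohort(spec)

props = cohort_properties(volumes, records, seed=42)   # networks, ~30 s
print(props[['id', 'age', 'sex', 'n_nodes', 'gamma', 'lambda', 'sigma']].head(4).round(3))

smoothed = [gaussian_smooth(v, 4.0) for v in volumes]
x, _ = vectorize_volumes(smoothed)
res = BrainAgeModel(x, props['age'].to_numpy(), n_components=20, folds=10).fit(seed=42)
print(res.summary())

table = props.assign(predicted_age=res.predicted, brain_pad=res.brain_pad)
report = run_full_analysis(table)      # table analogues as DataFrames
```

Output:

```
         id     age sex  n_nodes  gamma  lambda  sigma
0  sub-0001  65.569   F      304  1.489   1.027  1.449
1  sub-0002  67.193   F      304  2.515   1.096  2.294
2  sub-0003  62.177   M      352  1.587   1.072  1.481
3  sub-0004  78.747   M      304  1.113   1.021  1.090

Brain-age model (PCA + linear SVR, cross-validated)
===================================================
subjects                    60
folds                       10
components                  20
MAE (years)              3.978
RMSE (years)             5.015
r(pred, age)             0.972
mean brain-PAD (y)      -0.049
```

Every subject's network is small-world (γ > 1, σ > 1), the properties
decline with age (compare sub-0004, age 79, γ = 1.11, with the younger
subjects), men carry more nodes than women, and the cross-validated
brain-age model recovers chronological age to about 4 years MAE with r ≈
0.97 and an unbiased mean brain-PAD.

The same pipeline is scriptable from the shell:

```bash
sgmnet all --n 60 --seed 42 --out run/     # simulate → network → brainage → analyze
```

which writes NIfTI volumes, the per-subject properties CSV, brain-age
predictions and metrics, and the four statistical table analogues with a
run manifest.

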