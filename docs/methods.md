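# Methods

This note documents the statistical model, the synthetic-data calibration and
the numerical choices made in `morphozone`. Everything stated here is either
a definition or a property verified by the test suite; no empirical claims
beyond what the code computes are made.

## Superimposition

Partial generalized Procrustes analysis (GPA): each configuration is centered,
scaled to unit centroid size, and rotated to the current consensus by the
singular-value-decomposition solution constrained to proper rotations
(det = +1; no reflections). The consensus is re-estimated and re-normalized
each iteration until the summed squared deviation changes by less than a
relative tolerance of 1e-10 (with a 1e-12 absolute floor so exact fits, whose
deviation is pure rounding noise, terminate). Aligned shapes are projected
into the tangent space of the consensus `m` by `x ← x − (x·m − 1)m`.
Configurations whose landmarks are coincident or collinear raise a
`DegenerateConfigurationError` because the optimal rotation is
underdetermined.

## Symmetry decomposition

*Object symmetry* (single bilaterally symmetric structure with `k` landmark
pairs and `l` midline landmarks): each specimen enters one joint GPA twice —
as digitized and as its reflection through the symmetry plane with left/right
labels swapped. The symmetric component is the per-specimen average of the
two aligned copies; the asymmetry component is half their difference. The
symmetric shape space has dimension `3k + 2l − 4`, the asymmetry space
`3k + l − 3`; the decomposition attains these ranks exactly (checked to
singular-value precision in the tests).

*Matching symmetry* (separately digitized left/right structures with `k`
landmarks each): left configurations are reflected and all sides enter one
joint GPA; the symmetric component is the per-specimen side average, the
asymmetry half of (right − reflected left), and centroid size the mean of the
two sides. Symmetric dimension `3k − 7` (the asymmetry space has the same
dimension as the symmetric one because there is no midline constraint).

An all-midline object scheme (`k = 0`, `l ≥ 3`) is accepted: its
configurations lie entirely in the symmetry plane, so the template is planar
by construction and the dimension formula reduces to `2l − 4`.

**Fluctuating asymmetry (FA)** scores are the Procrustes-norm deviations of
each specimen's asymmetry component from the cohort mean asymmetry (the
directional-asymmetry estimate). A shared directional asymmetry added to
otherwise identical specimens yields exactly zero FA; when specimens also
differ symmetrically, per-specimen alignment introduces a second-order
coupling, so "zero" holds only to that order (both facts are tested).

## Statistics

- **Hotelling T²** (two samples, `p` variables): pooled covariance,
  `F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2))` on `(p, n₁+n₂−p−1)` degrees of freedom.
  Near-singular pooled covariances (condition number > 1e12) are rejected
  with a request to retain fewer components. Cross-checked against an
  external implementation and a 20,000-draw label-permutation oracle.
- **Per-pair PCA**: for every group comparison a PCA is re-fit on the pooled
  individuals of the two groups and the leading 10 PCs retained. Retention
  is capped at `n_pair − 3` (with a logged warning) so that the Hotelling
  `df₂ ≥ 1` and the leave-one-out discriminant's within-class scatter stays
  nonsingular; the cap never binds for comparisons with ≥ 13 specimens.
- **Discriminant cross-validation**: two-class linear discriminant (pooled
  within-class covariance, class-proportional priors) refit with each
  specimen held out in turn; the misclassification fraction is reported.
  Note that on data with no class signal this estimator is anti-learning
  (error above 50 %), a known artifact of proportional priors under
  leave-one-out resampling.
- **Holm step-down** correction over each family of pairwise tests (exact
  implementation, verified against brute force and statsmodels).
- **Permutation regression of shape on a covariate**: least squares per
  coordinate; the statistic is the predicted sum of squares, compared with
  its distribution under random permutation of the covariate (p-values use
  the (b+1)/(m+1) estimator, so the smallest attainable p is 1/(m+1)).
  Projection scores — centered shapes projected on the unit coefficient
  vector — provide the univariate visualization.
- **Between-group PCA**: eigenvectors of the (unweighted) group-mean matrix;
  individuals are projected onto the same axes.
- **Mantel test** between the group-level Procrustes and genomic distance
  matrices: Pearson correlation of upper-triangle entries, two-sided
  simultaneous row/column permutation null. The *near-pairs subset*
  (genomic distance < 20 percentage points) is **not** a complete distance
  matrix, so for it the pair values themselves are permuted — a plain
  permutation correlation, not a Mantel test. This is a deliberate,
  documented deviation.
- **Direction tests**: pairwise group shape-change vectors are oriented from
  the group with lower to the group with higher mean admixture and compared
  to the pooled *mus*→*dom* reference vector. The null CDF of the angle
  between two independent uniform random directions in `d` dimensions is
  evaluated in closed form with the regularized incomplete beta function
  (`P(Θ≤θ) = ½ I_{sin²θ}((d−1)/2, ½)` for θ ≤ 90°); `d` defaults to the full
  symmetric shape-space dimension. Validated against 10⁵-draw Monte Carlo.
- **Per-group phenotypic variance** uses the summed squared deviations from
  the group mean divided by `n − 1`; its square root is also emitted.

Every randomized procedure takes an explicit integer seed; there is no
global random state, and identical seeds give bit-identical results.

## Synthetic-data generator

The generator produces raw landmark configurations (with nuisance rotation,
translation and scale applied) whose *expected* structure is fully known:

```
symmetric deviation = h·(dom − mus)                 (admixture, additive)
                    [+ h(1−h)·dominance vector]     (optional nonadditive term)
                    + family effect (shared within family)
                    + sex effect (males)
                    + slope·(CS − mean CS)·allometry vector
                    + isotropic residual (symmetric tangent space)
asymmetric deviation = directional-asymmetry vector + isotropic FA noise
```

All deviations live in orthonormal bases of the symmetric and asymmetric
tangent spaces at the *mus* template (similarity modes — translations,
scaling, rotation generators — projected out), so Procrustes-unit magnitudes
are exact by construction. Admixture proportions `h` are drawn uniformly
within each specimen's decile; the per-decile specimen, family and male
counts default to the study design (6, 39, 67, 23, 31, 26, 31, 0, 9, 17
specimens per decile; decile 7 unobserved).

**Calibration** is analytic, not tuned: the admixture variance
`Var(h)·‖dom−mus‖²` is computed in closed form from the decile design, the
total non-allometric symmetric variance is set to make admixture the
requested fraction of it, the sex effect scale follows from the male
fraction via `p(1−p)`, the family and residual standard deviations split the
remaining variance per dimension, the allometric slope converts a
fraction-of-total target into Procrustes units per unit centroid size, and
the FA noise standard deviation is `target mean FA / √dim`. Realized
variance shares are recorded in the `TruthRecord` for every dataset.

## Numerical choices

- Tolerances: GPA convergence 1e-10 (relative); rank decisions at
  1e-8 × largest singular value; distance-matrix symmetry checks at 1e-10.
- Permutation p-values use the (b+1)/(m+1) estimator throughout.
- Exact Mann–Whitney enumeration when both groups have ≤ 8 untied
  observations; normal approximation with tie correction otherwise.
- Pipeline stages run in a fixed order and any failure is re-raised with the
  stage name; groups with fewer than 2 specimens are dropped from pairwise
  testing with a logged warning rather than aborting the run.

## Scope and limitations

- The generator models the *phenotypic consequences* of polygenic admixture
  only: no allele-level simulation, linkage or selection, and no pedigree
  structure beyond a shared family shape deviation.
- Residual and FA noise are isotropic within their tangent spaces; real
  within-group covariance is anisotropic, so covariance-structure estimands
  are out of scope.
- The symmetric component is analyzed in the tangent space; all distances
  are tangent-space (approximately Procrustes) distances, appropriate for
  the small shape variation simulated here.
- The near-pairs correlation is a permutation Pearson correlation, not a
  Mantel test (see above).
- Geographic cline fitting, genotype calling and 3D visualization are
  out of scope; figure exports are data layers only.
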