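# Methods

## Object-symmetry decomposition

A 2D landmark configuration X (k landmarks) with *object symmetry* carries
its left–right structure internally: a set of bilateral pairs (l, r) and a
set of midline landmarks, with k = 2p + m. The mirrored-relabelled copy of X
negates the first coordinate and swaps the members of every pair. The
superimposition is a doubled generalized Procrustes analysis (GPA): the 2n
configurations (originals plus mirror copies) are centered, scaled to unit
centroid size, and iteratively rotated to a consensus that is re-estimated
as the coordinate-wise mean, symmetrized by averaging with its own
mirror-relabelling, and re-scaled to unit size each round. Because the
reflection used is about the coordinate axis x = 0, the symmetrized
consensus is automatically axis-aligned; the only remaining frame ambiguity
is a 180° rotation, resolved by a deterministic index-weighted sign rule so
repeated runs are bit-identical.

Each aligned shape splits exactly into a symmetric component
S = (original + mirror)/2 and an asymmetric component
A = (original − mirror)/2. A is exactly anti-symmetric under
mirror-relabelling, has zero x-sum (centering) and is orthogonal to the
rotation tangent at the consensus (rotation optimality), so the A vectors
live in a (2p + m − 2)-dimensional subspace; the symmetric deviations span
another 2p + m − 2 dimensions, and the two add up to the full shape-space
dimension 2k − 4. The mean of the A is the directional asymmetry (DA);
deviations A − DA are the fluctuating asymmetry (FA).

Assumptions: variation is small relative to the curvature of shape space,
so components are used in the linearized coordinate-difference space without
an explicit tangent projection — at facial-asymmetry magnitudes (‖A‖ of
order 1–2% of centroid size) the difference is far below the other error
sources. Scaling follows the partial-Procrustes convention (configurations
pinned at unit centroid size); `full_procrustes=True` enables per-iteration
optimal rescaling for sensitivity analysis.

## Procrustes ANOVA

The two-factor (individual × side) table partitions the doubled dataset's
squared Procrustes variation:

| effect            | SS                    | df              |
|-------------------|-----------------------|-----------------|
| individual        | 2 Σ‖S_i − S̄‖²         | (n−1)(2p+m−2)   |
| side              | 2n‖DA‖²               | 2p+m−2          |
| individual × side | 2 Σ‖A_i − DA‖²        | (n−1)(2p+m−2)   |

These sum *exactly* to the total SS of the 2n aligned configurations around
their grand mean, which equals the mean symmetric component S̄. The returned
unit-size consensus differs from S̄ by a scale factor of order the shape
variance, so the package defines total SS around the grand mean — the exact
identity is preferred over agreement with the display consensus. With
replicate digitizations an error stratum (within-specimen variation of S and
A, df (N − n)(2k−4)) is appended and the decomposition stays exact; with one
image per specimen (the usual situation) no error stratum exists and no
error correction of the FA mean square is possible.

## Individual asymmetry scores

Each specimen's FA deviation d_i = A_i − DA (flattened) is scored two ways:

* **Mahalanobis score** — sqrt(Σ_j proj_ij²/λ_j) over the eigenpairs of the
  sample covariance of the d_i (n−1 divisor) with eigenvalues above
  `eig_tol` (default 1e-10) times the largest. Standardizing by the observed
  covariance removes anisotropic variation that biases raw Procrustes
  distances. For sample Mahalanobis norms the mean squared score is
  identically r(n−1)/n (r the retained rank), so sample means sit near √r —
  e.g. ≈ 9 for an 83-landmark face (r = 81), ≈ 5.9 for the 36-landmark eye
  region (r = 34) — and group structure appears as deviations around that
  level. The rank is truncated empirically rather than set to the
  theoretical 2p+m−2 so near-degenerate data cannot produce explosive
  scores; the theoretical dimension is reported alongside.
* **Procrustes score** — the plain norm ‖d_i‖, in Procrustes-distance units.

`remove_da=True` (default) scores fluctuating asymmetry sensu stricto;
`remove_da=False` retains the directional contribution for total-asymmetry
scores. In that case the eigenbasis still comes from the centered covariance
(a covariance by definition); any DA component outside the FA-variation span
is invisible to the Mahalanobis variant but present in the Procrustes one.

## Group comparison

CVA and between-group Mahalanobis distances are computed in the principal
subspace of the flattened asymmetric components (eigenvalues above
`eig_tol`·max), because 2k exceeds the usable rank min(n − g, 2p + m − 2).
The pooled within-group covariance W (divisor n − g) is pseudo-inverted by
eigenvalue truncation; canonical axes solve B v = λ W v in the whitened
subspace and are returned in the original coordinate space.
D(a,b) = sqrt((μ_a−μ_b)ᵀ W⁺ (μ_a−μ_b)); with two groups
T² = (n_a n_b/(n_a+n_b)) D² recovers Hotelling's statistic exactly
(cross-checked in the tests against an independent implementation). At
n ≈ 30/group in a ~50-dimensional retained subspace these distances carry a
substantial upward small-sample bias; the permutation test shares that bias
under the null, which is why inference relies on permutations rather than
on the distances themselves.

The permutation test is pairwise (only the two groups under comparison are
relabelled), with the observed distance computed from the same two-group
pooled covariance as the permuted ones and
p = (1 + #{D_perm ≥ D_obs})/(rounds + 1) — never exactly zero, bounded below
by 1/(rounds+1). Default 10,000 rounds; an explicit seed is mandatory in the
pipeline. No multiple-testing correction is applied to the pairwise matrix
(raw pairwise p-values are the convention in this literature); Bonferroni or
Holm can be applied downstream by the user.

## Score statistics

Two-way fixed-effects ANOVA of scores on sex × ethnicity uses Type II sums
of squares — appropriate for mildly unbalanced designs (29 vs 30 per group)
when the interaction is weak; under perfect balance it coincides with
Type I (tested). Shapiro–Wilk (residuals) and Bartlett (cells) are reported
as diagnostics only and never switch methods automatically. Post hoc
comparisons use the Tukey–Kramer studentized-range procedure (unequal n).

The database contrast uses a Welch two-sample t-test with a studentized
null-shift bootstrap: both samples are shifted to the combined mean,
resampled with replacement B times (default 1000), and the Welch statistic
recomputed; p = (1 + #{|t*| ≥ |t_obs|})/(B + 1). The 95% CI is the
percentile interval of the mean difference over the unshifted resamples
(same resampling indices). Percentile rather than BCa was chosen as the
plainest interval consistent with this scheme. Classical and bootstrap
p-values are always reported together. Seeding uses one child stream per
sample (`SeedSequence.spawn`); passing an explicit (seed_x, seed_y) pair
makes the procedure exactly exchangeable under argument swap.

## Synthetic data generator

`simulate_dataset` draws specimens as

  template + group symmetric offset + DA + group DA offset + FA + noise,

then applies an arbitrary similarity transform (rotation U(0, 2π),
log-normal scale with σ_log = 0.3, translation U(−2, 2)²). Symmetric and
asymmetric subspace bases are built explicitly from the pair/midline
structure with the four nuisance directions (translations, rotation, scale)
removed at the template, so planted vectors are exactly recoverable. All
scales are in units of template centroid size; `fa_scale` is the
per-dimension SD inside the asymmetric subspace (planted FA norm
≈ σ_FA·√(2p+m−2)). Group-specific DA offsets let group means differ in the
asymmetric subspace, which is what pairwise permutation tests detect; σ_FA
differences move score means but not component means. An optional seeded
anisotropic FA covariance exercises the Mahalanobis-vs-Procrustes score
distinction.

The shipped demo (`demo_spec`) mirrors a two-database design: five groups
of 30 (15/15 by sex) in one database and one admixed group of 29 (13/16) in
the other, 83 landmarks (39 pairs + 5 midline), 179 specimens in total. The
divergent group carries a DA offset of 0.007 and a ~10% lower σ_FA
(0.0018 vs 0.002); shared DA 0.008, symmetric offsets 0.02, digitizing
noise 0.0005 — values chosen once to give realistic facial-asymmetry
magnitudes (FA ≈ 1–2% of centroid size, between-group distances of order
3–5) and a power level at which the database contrast is detectable but not
trivial.

What the generator does **not** emulate: detector-specific landmark error
structure (correlated, landmark-dependent noise), allometry, age structure,
non-Gaussian FA, and any real population differences — passing tests
demonstrate correctness and calibration of the machinery on data satisfying
its assumptions, not conclusions about real faces.

## Numerical choices and problem sizes

* GPA: `tol` 1e-10 on the consensus Frobenius change, `max_iter` 100
  (typical convergence: 4–8 iterations); non-convergence is a warning that
  reports the final change.
* Eigenvalue truncation: relative threshold 1e-10 everywhere a covariance is
  inverted; retained ranks are logged.
* Degenerate inputs: all-zero asymmetry yields zero scores with a warning
  (no division by zero); constant score vectors yield zero SS and NaN F with
  a warning; coincident-landmark configurations raise an alignment error.
* The packaged 83-landmark layout (contour 19, brows 16, eyes 20, nose 10,
  mouth 18) is this package's own synthetic layout with symmetry-closed
  feature blocks; commercial detector layouts differ, and users supply their
  own map/features JSON for real data.
* Tests and the acceptance script use reduced Monte-Carlo sizes chosen as
  the smallest that leave comfortable margins on the calibration bounds:
  permutation calibration at 500 replicates × 199 rounds, parameter
  recovery at 20–100 seeds, demo inference at 299–999 permutation rounds
  and 499–999 bootstrap replications.

## Known limitations

* 2D object symmetry only: no matching symmetry (paired separate
  structures), no 3D, no semilandmark sliding.
* No tangent-space projection (see above); inappropriate for very large
  shape variation.
* The pairwise permutation test permutes raw labels; covariate-adjusted
  permutation schemes are out of scope.
* "Error-corrected" FA requires replicate digitizations; with single images
  the FA stratum includes digitizing error inseparably.
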