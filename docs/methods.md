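# Methods

This note documents the statistical model behind `facegrowth`, the defaults
and why they were chosen, the numerical decisions, and the limits of what
the synthetic-data tests establish.

## Data model

A training cohort is *n* faces on a shared template topology of *k*
vertices, each with age (decimal years) and sex.  Correspondence is
positional — vertex *i* is the same anatomical point on every face — and is
produced upstream by non-rigid surface registration; this package consumes
already-corresponded meshes and never re-matches points.  Coordinates are
millimetres; the mapping of x/y/z to medial–lateral, superior–inferior and
anterior–posterior is carried explicitly (`AxisConvention`, default x/y/z
respectively) and stored in every model manifest.

All sex-specific models are built from a single generalized Procrustes
analysis (GPA) of the training set: shapes are centred and iteratively
rotated onto the evolving consensus until the consensus RMS change falls
below 1e-8 mm (at most 100 iterations; exceeding the budget raises an
error with diagnostics).  Rotations are constrained proper (det +1): faces
are chiral, reflections are never admissible.

**Scaling during the training GPA is off by default.**  Size growth is the
dominant age signal, and keeping shapes in mm means expected faces,
pointwise SDs, signatures and normal-equivalent differences all have
physical units.  Unit-size scaling (each aligned shape normalized to unit
centroid size) is used where shape must be averaged independently of size —
morph construction — and is available as a flag, recorded in the model
manifest, for users whose capture systems do not preserve absolute scale.

## Expected faces: local shape-on-age regression

The expected face at target age *t* is a Gaussian-kernel locally weighted
linear regression of the aligned coordinates on age.  With a univariate
predictor, a one-component PLS regression of the coordinate block on age
yields exactly the same predictions as per-coordinate weighted least
squares, so the latter is implemented directly (no iterative fit):

    w_i     = exp(-(a_i - t)^2 / (2 sigma^2))
    slope_j = sum_i w_i (a_i - a_bar_w)(x_ij - x_bar_wj)
              / sum_i w_i (a_i - a_bar_w)^2
    E_j(t)  = x_bar_wj + slope_j (t - a_bar_w)

The equivalence is asserted against an independent weighted-OLS solve in
the test suite.

**Adaptive bandwidth.**  The kernel width must widen where training data
are sparse.  The rule implemented: the smallest `sigma >= sigma_floor`
whose Kish effective sample size `(sum w)^2 / sum w^2` reaches
`min_effective_n`, found by doubling search plus bisection to 1e-4 years
(the effective size is non-decreasing in sigma).  Defaults:
`sigma_floor = 1` year (below which age-binning noise, not biology,
dominates) and `min_effective_n = 200`, sized for normative cohorts of
thousands; desk-scale experiments on simulated cohorts of a few hundred use
proportionally smaller targets (the tests use 100–150 at n = 500).  Both
values are recorded in the model manifest.  Evaluating a model outside the
training age range is refused by default (`ExtrapolationError`) because a
local linear trend has no support there.

**Age-adjusted residuals.**  Normal variation at age *t* is estimated from
the residuals of the same weighted fit, with each training face recentred
on the prediction at *its own* age:
`r_i = x_i - (E(t) + slope (a_i - t))`.  This removes the local age trend,
so residuals are displacement-from-expected at each subject's own age,
expressed in the target-age frame; their weighted mean is zero by the
normal equations.

## Models of normal variation

**Pointwise standard deviations** are the weighted RMS of the residual
displacements per vertex: along each anatomical axis, along the
expected-surface vertex normal (area-weighted, outward-oriented), and in
total magnitude — `sd = sqrt(sum_i w_i d_i^2 / sum_i w_i)`.  This form
reduces to the ordinary (uncentred) SD under equal weights and is invariant
to rescaling all weights.  Because the axis decomposition is orthonormal,
`sd_magnitude^2 = sd_ml^2 + sd_si^2 + sd_ap^2` holds exactly and is
asserted per build.

**Statistical shape models.**  Residual rows are scaled by
`sqrt(w_i / sum w)` and decomposed by SVD *without column centering or
standardization*; right singular vectors are the modes, squared singular
values the per-mode variances (with the row scaling these are exactly the
weighted variances along the modes, which is what the Mahalanobis distance
assumes).  The smallest leading set of modes with cumulative explained
variance >= 98% (configurable) is retained, capped at
`floor(effective_n) - 1` modes as a small-sample guard.  Note the cap, not
the variance criterion, can bind for tiny cohorts; the sum of *all* mode
variances equals the total weighted residual variance (conservation, tested
with full retention below the cap).

## Patient assessment

A patient is first superimposed onto the expected face of the nearest grid
age (nearest-age lookup is logged, never interpolated — with 0.3-year
spacing the interpolation error is negligible against the SDs) by ordinary
Procrustes, with scaling matching how the model was built.

**Facial signature.**  Per-vertex z-scores: each directional component of
the displacement divided by the corresponding pointwise SD; the
normal-direction score is signed outward-positive.  Vertices with zero SD
are masked (NaN) rather than inflated.  Signatures are linear in the
displacement field by construction.  Export writes the patient geometry as
PLY with the z_normal scalar; the documented display convention is a
symmetric ±2 colour range.

**Normal equivalent.**  Iteration: (1) weighted least-squares projection of
the displacement onto the modes (per-vertex weights replicated to
coordinates; equal weights reduce to the orthogonal projection);
(2) if the chi-square tail of `D^2 = sum c_j^2 / lambda_j` (m degrees of
freedom) falls below `p_crit = 0.05`, the coefficient vector is rescaled by
`sqrt(D^2_crit / D^2)` — in standardized coordinates this is the exact
nearest point of the critical Mahalanobis ball, keeping the projection's
direction; (3) reconstruct; (4) per-vertex residual magnitudes update the
weights through a Gaussian kernel with robust scale `1.4826 x median
residual`, so poorly reconstructed (abnormal) regions lose influence on the
next projection.  Convergence: reconstruction RMS change < 1e-4 mm or 10
iterations.  The weight-update kernel is a design choice — the requirement
is only that badly fitting regions are down-weighted — chosen because it is
smooth, scale-free (MAD normalization) and degrades gracefully to uniform
weights when residuals are uniform.  One iteration with equal, never-updated
weights is exposed as `closest_control`.  Invariants asserted in tests:
the final tail probability never drops below `p_crit`; the algorithm is
idempotent on its own output; the radial rescaling agrees with a KKT
(Lagrange-multiplier) solution of the constrained problem in the
standardized metric.

**Morphs.**  Average faces of small groups: GPA *with* unit-size scaling,
vertex-wise arithmetic mean, rescaled so the centroid size equals the mean
of the members' original sizes; the morph's age is the members' mean age.

## The synthetic world

`facegrowth.simulate` generates corresponded "faces" with analytic ground
truth so that every estimator can be checked for parameter recovery.  The
stated world:

| quantity | default | rationale |
| --- | --- | --- |
| mesh | 500-vertex deformed ellipsoid (axes 0.85/1/0.75), Fibonacci lattice + convex-hull triangulation | desk-scale stand-in; the algorithms are dimension-independent |
| growth | radius 50 → 80 mm with time constant 8 y, plus an anterior "chin" bump growing with time constant 10 y | smooth, monotone, decelerating; facial growth is largely complete by late adolescence |
| variation | 5 smooth orthonormal modes, score SDs (30, 22, 16, 12, 9) mm at age 0, × (1 + age/60) | per-vertex displacement SDs ~1.5–3 mm, matching reported facial RMS variation; variation increases with age; every mode's variance clears the nuisance terms so the low-rank structure is identifiable |
| sensor noise | 0.3 mm isotropic per coordinate | sub-millimetre repeat-measurement error of surface registration |
| pose jitter | 5°, 5 mm, zero-mean | removed exactly by GPA |
| scale jitter | 0.3% SD | calibration-level scale error of 3D photogrammetry; *not* removed by pose-only GPA, therefore included in the analytic ground-truth SDs |
| ages | mixture: 35% on the young fifth, 45% young-adult, 20% older, of [0, 90] | pooled normative collections are dominated by children and young adults, sparse in the elderly |

Mode fields are white Gaussian vector fields smoothed on the surface, with
the 3 translational, 3 infinitesimal-rotational *and* the radial (scaling)
fields projected out before orthonormalization.  Without that projection
the population covariance eigenvectors would be mixtures of the modes and
the scale-jitter direction, and "recovering the generative modes" would be
ill-posed rather than a property of the estimator.

**What a green parameter-recovery test establishes — and what it does
not.**  Recovery tests compare, at well-sampled adult ages (25/30/35, where
the growth trend's curvature is small relative to the kernel window), the
fitted expected face to the generative mean *after rigid superimposition* —
GPA fixes the frame only up to a rotation, and the Procrustes distance is
the standard shape metric — plus directional SDs (relative L2 over
vertices) and the principal angles between the fitted and generative mode
subspaces.  Passing them shows the estimators are consistent under the
generator's assumptions: Gaussian low-rank variation, isotropic noise,
exact correspondence.  Real data violate all three (registration error is
spatially correlated, variation is not Gaussian, correspondence drifts),
so green tests validate the *machinery*, not clinical accuracy.  Likewise
the dysmorphism-detection test isolates the injected signal (the subject's
normal-range variation is switched off); a single real patient's signature
carries ~N(0,1) z-noise at every vertex on top of any true signal.

Kernel local-linear regression has bias `~ 0.5 g''(a) sigma^2` wherever the
growth trend is curved, and the trend misfit contributes a structured
radial residual component growing like `sigma^4`; both are intrinsic to the
method (on any data), which is why the variable bandwidth keeps sigma small
where data allow and why recovery tolerances are evaluated at ages past the
growth spurt.

## Numerical choices

* Ordinary Procrustes via SVD of the cross-covariance (Kabsch/Umeyama),
  det-+1-corrected; rank < 2 configurations raise (reflection ambiguity).
* GPA consensus initialized at the mean of the centred inputs, making the
  result exactly invariant to input order.
* Weighted projections solve the normal equations with weights normalized
  by their maximum; exact singularity raises `SingularProjectionError`.
* Archives store arrays as npz (bitwise round trip asserted) with a
  human-readable JSON manifest; a format-version field guards against
  reading future layouts.
* All randomness flows through `numpy.random.default_rng` seeds; cohorts,
  archives and pipeline outputs are byte-reproducible given a seed.

## Known limitations

* Cross-sectional only: no within-subject longitudinal modelling, and no
  covariates beyond age and sex (in particular, no ancestry-specific
  models — the single largest caveat for clinical use).
* No non-rigid registration: correspondence quality is inherited entirely
  from upstream processing.
* Nearest-grid-age lookup assumes a dense grid; with coarse grids the age
  mismatch can approach half the grid step.
* The normal equivalent's reweighting has no global optimality guarantee;
  it is a fixed small number of descent-like iterations with a statistical
  constraint, which matches its intended use as a visual/planning aid.
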