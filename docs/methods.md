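# Methods

## Model

A subject's recording is a trajectory of landmark configurations: frames
of M labelled points in Dim ∈ {1, 2, 3} dimensions at strictly increasing
time stamps. Because captures differ in frame count and sampling, each
subject's time axis is affinely mapped to [0, 1] and every coordinate
channel is fitted with an interpolating spline and evaluated at T equally
spaced grid times. The resampled frames are flattened time-major
(element index `t·(Dim·M) + m·Dim + d`) into a feature vector of length
L = Dim·M·T; the univariate case is L = T. Resampling treats time as
continuous in the spirit of functional PCA, but the decomposition itself
operates on the regular grid: no basis expansion of the covariance
operator is performed.

**Single-level PCA.** The sample covariance over all n subjects (divisor
n−1) is eigendecomposed into eigenvalues θ_l ≥ 0 (descending) and
orthonormal modes ψ_l. Scores of a vector X are a_l = (X−η)·ψ_l;
reconstruction is η + Σ a_l ψ_l.

**Two-level mPCA (= between-group PCA).** With p groups of sizes n_j:

* group means η^j; grand mean η = (1/p) Σ_j η^j — deliberately the
  *unweighted* average of group means, not the pooled subject mean;
* level 2: per-group covariances about η^j (divisor n_j − 1) pooled with
  equal weight 1/p per group. This treats each group alike irrespective
  of size; the maximum-likelihood n_j/n weighting is available via
  `within_weighting="size"` for comparison but is not the default;
* level 1: covariance of the group means about η with divisor p−1. Its
  rank is at most p−1, so with two groups exactly one nonzero
  between-group eigenvalue can exist;
* each level is eigendecomposed independently. Orthonormality holds
  within a level only; nothing relates ψ^1 to ψ^2.

**Score fitting.** The expansion
X ≈ η + Σ_{l≤m1} a_l¹ψ_l¹ + Σ_{l≤m2} a_l²ψ_l² is fitted by minimizing the
squared residual over all scores jointly. The objective is quadratic, so
the least-squares solution is the global optimum. The two levels' modes
can be collinear — in the bundled generators the between-group direction
lies exactly in the span of the within-group modes — and then the
minimizer is not unique. The tie is broken by minimizing the
standardized-score norm Σ a_l²/θ_l among residual minimizers
(equivalently: min-norm least squares in the basis of √θ-scaled modes).
Under the implied hierarchical Gaussian model this is the MAP attribution
of shared directions: variance flows to the level whose eigenvalue is
larger, so between-group structure lands on level 1 and noise on level 2.
A raw min-norm tie-break would instead split group separation evenly
across levels and destroy the interpretability of per-level scores.
Zero-variance modes, if explicitly retained, enter the design unscaled.

**Standardization.** Scores are standardized as a_l/√θ_l, making the
training-set standardized score variance ≈ 1 per mode and
η ± 1.96·√θ_l·ψ_l an approximate 95% interval with respect to mode l.
Standardizing a mode whose eigenvalue is zero (under the tolerance below)
raises a `DegenerateModeError` rather than dividing by ~0.

**Modes of variation.** `mode_trajectory(level, l, c)` returns
η + c·√θ_l·ψ_l, exportable as a T-long table of M×Dim frames. Exported
numbers are never smoothed; any visual smoothing is left to the consumer.

## Numerical choices

* **Spline**: interpolating spline per coordinate channel via
  `scipy.interpolate.make_interp_spline`; cubic with not-a-knot end
  conditions for ≥ 4 frames, degrading to quadratic/linear for 3/2
  frames instead of failing. Not-a-knot reproduces cubic polynomial
  trajectories exactly (a natural spline would not) and interpolation
  reproduces data already on the grid. Endpoints map exactly onto the
  grid ends, so no extrapolation occurs. Smoothing splines are out of
  scope.
* **Eigen-solver**: dense symmetric `eigh` when the number of
  (weighted, centered) observation rows r ≥ L; otherwise the snapshot
  method on the r×r Gram matrix, mapping eigenvectors back through the
  factor. Both levels of mPCA are expressed as factor matrices so the
  same machinery serves K¹, K² and single-level K.
* **Nonzero tolerance**: θ counts as nonzero iff
  θ > 1e-8 · max(θ_max, 1). Eigenvalues are clamped at 0.
* **Sign convention**: each mode's largest-magnitude entry is made
  positive, for backend-independent output. Within a degenerate
  eigenspace the backend's basis is kept; tests avoid depending on it.
* **Singleton groups** are permitted (the "every subject its own group"
  nested reading): they contribute zero within-group covariance, with a
  warning. Level 1 still requires p ≥ 2.
* **Small-sample pathology**: between-group PCA can manufacture spurious
  group separation when n_j < L. Assembly and fitting emit a
  `SmallSamplePathologyWarning` in that regime; no correction is applied.

## Synthetic generators

All generators are deterministic given their seed; the noiseless
structure is seed-independent.

* **Sine wave** (univariate, two groups): x(t) = (A_j + ε_i)·sin(2πt/P_j)
  with periods (2, 1.5), amplitudes (0.5, 0.4), ε_i ~ N(0, 0.03²) drawn
  once per subject, T = 101 regular samples on [0, 2] (one full period of
  group 1; the observation window is a package choice). "Magnitude 0.03"
  is read as a standard deviation. Between-group variance exceeds
  within-group variance by ~two orders of magnitude since variance scales
  with amplitude squared. Under this scalar amplitude noise each group
  contributes exactly one within-group direction, so the common level-2
  covariance has rank 2; a per-time-point variant
  (`noise_mode="pointwise"`) is provided because published analyses of
  this construction have reported three nonzero within-group eigenvalues,
  which a scalar-noise reading cannot produce. The discrepancy is
  documented rather than resolved.
* **Blink** (16 2D landmarks, two classes): rest outline of two parabolic
  arcs (8 points each) through shared corner points, aperture profile
  f_c(t) = 1 + D_c·sin²(πt) with the blink class closing to 2% of rest
  aperture and the surprise class opening to 130% (both configurable,
  both back at rest at t ∈ {0, 1}). Per-subject noise scales the whole
  aperture trajectory: y_i = (1+ε_i)·f_c(t)·y_rest, mirroring the sine
  generator's amplitude noise. The per-class deviation directions differ
  (blink vs surprise profiles), giving exactly two nonzero level-2
  eigenvalues; scaling only the deformation term would collapse both
  classes onto one direction and rank 1. Default n_j = 10,000 per class.
* **Smile-like** (12 3D mouth landmarks, two sexes, 31 + 29 subjects): a
  *synthetic stand-in*, not a model of any real capture system. An
  elliptical lip outline is widened at the corners and pulled backward
  (negative z) along a sin²(πt) profile with per-subject amplitude noise;
  a per-subject resting-curvature coefficient (N(0, 0.25²)) makes mouths
  upturned or downturned — the dominant within-group mode; the
  between-sex offset is a small widening factor (default 5%) so group
  differences are weak by construction. Frame counts are irregular
  (100–250) with jittered time stamps to exercise resampling.

What the generators do *not* emulate: scanner noise, landmark placement
error, time-warping/phase misalignment across subjects, rigid rotation,
and any correlation structure beyond the single amplitude/curvature
factors. Passing tests therefore demonstrate the decomposition machinery
and its rank/dominance structure, not robustness to real acquisition
artifacts.

## Problem sizes and default parameters

Desk-scale runs use n_j = 1000 per group at T = 101 for both paper-style
generators; level ranks and dominance relations are invariant to this
choice, and the blink generator's n_j = 10,000 default remains available.
m₁ defaults to all nonzero level-1 modes; m₂ defaults to the smallest
number of level-2 modes reaching 95% of level-2 variance. The
±1.96·√θ₁² interval of the leading level-2 mode is assessed as coverage
of the mode-1 *score* of each subject's deviation from its group's fitted
trajectory (a prediction interval with respect to that mode); pointwise
curve coverage by the same band is a strictly harsher measure (≈80% on
the sine data) because the leading within-group mode mixes the two
groups' sine directions.

## Known limitations

* Exactly two levels; the containers and naming do not preclude an
  N-level generalization, but none is implemented.
* No Procrustes superimposition, size normalization or nonlinear time
  registration; centering removes per-frame translation only.
* No significance testing of between-group differences and no
  cross-validation guard against between-group-PCA pathologies beyond
  the sample-size warning.
* Group membership of new subjects is not predicted; classification is
  out of scope.
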