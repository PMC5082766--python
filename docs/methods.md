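# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the limitations of `adipobrain`.

## Scientific setting

In a cross-sectional adult cohort (ages 20–87), cerebral white-matter volume
follows an inverted-U lifespan trajectory — rising to a mid-life peak and
declining thereafter — while cortical surface area, mean thickness and fluid
intelligence decline near-linearly or with mild curvature. The question the
package operationalizes is whether adiposity shifts the white-matter
trajectory toward "older" values: at a given white-matter volume on the
descending limb, how much younger are overweight/obese subjects than lean
subjects with the same volume? That age gap is the brain-age difference
delta; positive values mean the heavier group's white matter resembles that
of an older lean brain.

## Penalized-spline regression

Each outcome is modelled as an unknown smooth of age plus unpenalized linear
covariates:

minimize over (θ, β):  ‖y − Bθ − Xβ‖² + λ‖D_d θ‖²

- **Basis.** Cubic B-splines on 22 equally spaced knot sites across the
  observed age range (20 interior), extended `degree` extra equally spaced
  knots beyond each boundary. The extension (rather than clamped, repeated
  boundary knots) keeps the Greville abscissae uniform, so the nullspace of
  the difference penalty maps exactly onto polynomials in age; with the
  default second-order penalty, λ → ∞ recovers the ordinary least-squares
  straight line. Basis dimension is `n_knots + degree − 1` (24 by default).
  Quantile knot placement is available for strongly non-uniform age samples.
- **Penalty.** Second-order differences of adjacent spline coefficients
  (units: outcome units; λ is dimensionless relative to the squared-error
  scale). First-order penalties are supported (`penalty_order=1`), under
  which the infinite-smoothing limit is a constant.
- **Smoothing selection.** Generalized cross-validation by default; REML
  under the mixed-model representation (spline coefficients as random
  effects) via `method="reml"`. Both are profiled cheaply through a
  Demmler–Reinsch orthogonalization, so each candidate λ costs O(p). Exact
  criterion ties are broken toward the smoother fit. The design is
  cross-sectional (one observation per subject), so no subject-level random
  effects exist beyond the spline's own random-coefficient reading.
- **Covariates.** Mean-centered and unpenalized; the fitted curve is reported
  at the covariate reference (sample or pooled means), so `fitted_grid` is
  the age trajectory of an average-covariate subject. Covariates constant in
  the analysis sample are dropped with a warning (unidentifiable next to the
  spline's intercept, which lies in the basis span); genuinely collinear
  designs raise an error. Missing data are handled by complete-case analysis
  with the dropped count recorded on the fit.
- **Inference.** Linear terms use the model-based covariance
  σ̂²A⁻¹(ZᵀZ)A⁻¹ with residual degrees of freedom n − edf, where
  edf = tr(smoother). The smooth is tested with an F ratio of the full model
  against the covariates-plus-intercept linear model using edf-based degrees
  of freedom. These are approximations standard for penalized smoothers; the
  test suite asserts their calibration by simulation (type-I error of the
  age×BMI interaction within (0.02, 0.09) at nominal 5%) rather than exact
  distributional claims.
- **Interaction and trait coding.** The pooled age×BMI interaction uses
  continuous mean-centered BMI by default; a lean vs overweight/obese group
  coding is available, and `test_group_effects` reports both the group offset
  ("trait") and the age×group ("trajectory") terms from one fit.

## Volume-matched brain-age difference

Group trajectories are fitted independently for lean and overweight/obese
subjects with pooled-mean covariate referencing and a shared 0.1-year grid on
the common age support. For each overweight/obese reference age a in the
evaluation window (37–87 years by default, configurable):

1. v = overweight/obese curve at a (descending limb only; earlier ages are
   flagged and excluded),
2. the lean curve is inverted at volume v, restricted to ages at or above the
   lean peak, by bracketing grid points and linear interpolation
   (`descending_only` rule),
3. delta(a) = matched lean age − a; negative values are clamped to zero
   (`clamped_zero`, switchable off), and volumes below the lean curve's
   oldest value truncate the matched age at the oldest grid age
   (`truncated_support`).

Truncation biases delta toward zero at the oldest evaluation ages — with a
true 10-year shift and an 87-year ceiling, reference ages above ~77 are
capped — which is why per-age rule flags are carried in every output and the
summary mean excludes truncated ages. Re-indexing the estimand from volume to
the overweight/obese age is a bijection on the descending limb and is the
form in which the curve is reported.

**Bootstrap.** Subjects are resampled with replacement within each weight
group (pooled resampling optional), both trajectories are refitted per
iteration, and the three rules are applied inside each iteration; bands are
elementwise percentile intervals (90% and 95% by default, 10,000 iterations
by default). Percentile intervals are the minimal-assumption choice for a
possibly skewed, clamped statistic. Two deliberate efficiency choices:

- λ is fixed at the full-sample per-group values inside the bootstrap, so the
  bands reflect sampling variability of the curves at the chosen smoothness
  rather than re-smoothing noise;
- resampling is implemented as multinomial weights with batched weighted
  normal equations, and covariates enter uncentered (exactly equivalent,
  since constants lie in both the spline span and the penalty nullspace) with
  the curve evaluated at the pooled covariate reference. A small ridge on the
  unpenalized block keeps iterations defined when a rare binary covariate
  becomes constant in a resample.

Iterations that produce no valid value at an age (e.g., no descending-limb
support) contribute nothing there; ages where fewer than half the iterations
are valid are flagged `ci_unavailable`.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a test
convenience; its defaults encode the cohort structure the analysis assumes.

- **Ages** uniform on 20–87 years; **sex** balanced; **ICV** normal per sex
  (1400/1550 ± 110 cm³), and volumetric outcomes scale multiplicatively with
  ICV so the covariate adjustment has real work to do.
- **BMI** is a truncated-normal with an age slope. The marginal mean and SD
  are solved numerically from the configured (lean, overweight, obese)
  proportions (0.51/0.31/0.18 by default) so that group membership emerges
  from BMI exactly as in the analysis; the default slope of
  0.11 kg·m⁻²·yr⁻¹ yields a population age–BMI correlation of ≈ 0.24 after
  truncation at 18.5. The underweight tail can be switched on to exercise
  the exclusion path.
- **White-matter volume**: lean subjects follow a concave quadratic peaking
  at 43 years with 470 cm³ and curvature 25/289 cm³·yr⁻² (so the curve passes
  445 cm³ at age 60); overweight/obese subjects follow the same curve
  evaluated at age + Δ with Δ = 10 years by default. A horizontal age shift —
  rather than a vertical volume offset — makes the true volume-matched delta
  identically Δ on the descending limb, which is the recovery target of the
  whole estimator. Additive Gaussian noise, SD 15 cm³. An asymmetric variant
  (different rising-limb curvature) is available for robustness checks.
- **Surface area / thickness**: linear declines; thickness carries a
  +0.02 mm offset for the heavier group and a gray–white-contrast
  measurement term. **Cattell**: quadratic decline with a brain-size term and
  ~2% missingness, exercising the complete-case path.
- **QC**: probability of a "poor" rating rises with age on the log-odds
  scale (0.04 per year around a 7% baseline); "adequate" ≈ 12%.
- **Covariate flags**: independent Bernoulli given weight group, with
  group-specific prevalences typical of a community aging cohort (e.g.,
  hypertension 8/20/38% in lean/overweight/obese).
- **Seeding**: one root seed; every column owns a fixed named substream, so
  adding a column never perturbs existing ones and identical configurations
  are byte-identical on disk.

What the generator does **not** emulate: longitudinal change, scanner/site
effects, joint dependence of the health flags on age within group,
non-Gaussian measurement error, and any regional (vertex-level) structure.
Passing tests therefore demonstrate that the estimator recovers known truth
under a clean cross-sectional shift model — not that real-cohort effect sizes
or p-values would be reproduced.

## Numerical choices and degenerate inputs

- Inversion uses linear interpolation between bracketing grid nodes; no
  spline re-evaluation between nodes, keeping bootstrap cost linear. Halving
  the grid step changes delta by less than the prior step.
- Non-monotone descending limbs (local re-increase) warn and use the first
  crossing from the peak; a first-crossing envelope (running minimum) makes
  the vectorized bootstrap path agree with the scalar operation.
- Peak ties break to the youngest age; flat curves raise a degenerate-
  trajectory error.
- Box-Cox requires strictly positive inputs and reports the profile-ML λ;
  Bland–Altman uses the conventional 1.96·SD limits of agreement and a
  paired test reported as F = t².
- Exclusions apply in the fixed order age → underweight → QC, one reason per
  subject, making the report counts deterministic and the operation
  idempotent.

## Problem sizes used in the test suite

The statistical acceptance checks run at the cohort scale the defaults
define: 50 cohorts for shift recovery, 400 replicates of n = 300 for
interaction calibration, and 200 cohorts × 500 bootstrap iterations for
interval coverage — sizes chosen to give stable Monte-Carlo estimates of each
property while the whole suite stays fast enough to run routinely.

## Known limitations

- The brain-age difference is the volume-matching construction only; no
  machine-learning chronological-age predictor is included or intended.
- Percentile (not BCa) bootstrap; with heavy clamping near the null the
  lower band is pinned at zero, which is informative but conservative.
- The F/t approximations inherit the usual edf-based caveats of penalized
  smoothers; calibration is verified by simulation under this generator, not
  guaranteed universally.
- With severe group imbalance or narrow age coverage the group fits refuse to
  run (support checks) rather than extrapolate.
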