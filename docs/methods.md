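# Methods

## Problem

Image-guided radiotherapy couches correct patient position in six
degrees of freedom (6 DOF): translations x (lateral), y (longitudinal),
z (vertical) in mm, and rotations yaw α, roll β, pitch γ in degrees.
Treatment-planning systems, however, evaluate robustness against
*translational* perturbations only. A rotation displaces a target by an
amount that grows with the distance R between the target (CTV centroid)
and the isocenter, the origin of couch rotations. This package
scalarizes 6-DOF setup errors into a one-dimensional positional
uncertainty as a function of R, so 6-DOF measurements can be compared
against scalar robustness settings (e.g. "is 3 mm enough?").

## The scalarization model

Let σx², σy², σz² (mm²) and σα², σβ², σγ² (rad²) be the per-DOF error
variances estimated across a cohort at one workflow timepoint
(unbiased n−1 sample variances, taken about the sample mean, so
systematic offsets inflate the sampled means rather than the
variances). For a target at distance R with isotropically distributed
direction, E[rᵢ²] = R²/3 along each axis, and a small rotation vector ω
displaces the target by δ = ω × r. The six variances fold into three
R-dependent total translational variances; to first order each
translational axis i receives (R²/3)·σⱼ² from the two rotations j
about the *other* axes:

    p̄ᵢ²(R) = σᵢ² + (R²/3) · Σ_{j ∉ axis i} σⱼ²     (mode "first_order")

A scalar sample of the overall error for one measured setup error
(x, y, z, α, β, γ) is then

    ‖(X, Y, Z)‖,  X ~ N(x, p̄x²), Y ~ N(y, p̄y²), Z ~ N(z, p̄z²),

i.e. the 3-vector norm of independent normals centred on the measured
translations with the R-dependent total variances. Repeating the draw
gives a *representative error* per measurement (mean of 1000 norms by
default; the mean is chosen because the downstream mixed models compare
group means; a median option exists) and, pooled over a cohort, the
95th percentile of the scalar error as a function of R.

Three transform modes are provided:

* `first_order` (default) — the cross-product derivation above, under a
  configurable machine rotation convention. Default convention: yaw
  about z, roll about y, pitch about x, applied intrinsically
  pitch→roll→yaw; all of this is configuration (`geometry:` block)
  because conventions vary by machine.
* `as_printed` — a published closed form of the same transform whose
  lateral line receives (β, γ), longitudinal (α, γ) and vertical (α, β),
  plus second-order product terms (σα²σβ², …). The memberships
  correspond to a different axis-naming convention than our default,
  and the product terms are ≤10⁻³ of the leading terms at clinical
  magnitudes (≤2°); the mode is kept for literal reproducibility.
* `exact_mc` — a Monte Carlo oracle: exact rotation matrices with
  normally drawn angles applied to isotropically oriented offsets of
  length R. The closed forms agree with this oracle to well under 1%
  relative for σ ≤ 2° and R ≤ 100 mm (verified on a 5×5 grid at 10⁶
  draws with equal per-axis rotational SDs, the regime where both
  closed forms coincide).

Note a deliberate property of the sampler, inherited from the procedure
it implements: each draw is centred on a *measured* error while also
carrying the full cohort variance, so the marginal spread of sampled
norms is √2 times the per-axis SD when the measured errors themselves
are draws from the cohort distribution. Users comparing the curve
against raw per-DOF statistics should keep this conditioning in mind.

## Percentile curves and bootstrap bands

For each R on the grid (default 0–100 mm by 25), the point estimate
draws n_sim = 2000 scalar samples, each centred on a record resampled
uniformly from the timepoint's measurements, and takes the empirical
95th percentile (linear interpolation between order statistics). The
confidence band resamples *patients* with replacement (n_boot = 500),
re-estimates the variance profile per replicate, and recomputes the
percentile; this respects the repeated-measures structure. Two interval
flavours exist because both appear in practice:

* `percentile` (default) — raw 2.5/97.5 bootstrap quantiles;
* `studentized` — bootstrap-t, with each replicate's pivot standardized
  by a nested patient bootstrap (n_inner = 20) inside that replicate.
  Duplicated patients are relabelled as distinct in the resampled
  cohort so the nested bootstrap sees its actual structure.

A finite bootstrap can place both band edges on one side of the point
estimate; the band is widened minimally so it always brackets the
estimate. Common random numbers are reused across the R grid, which
makes the estimated curve exactly flat when rotational variance is zero
and suppresses spurious non-monotonicity from Monte Carlo noise.

## Cohort statistics

* **Paired planar-vs-volumetric (2D vs 3D) tests.** Per DOF, a paired
  Wilcoxon signed-rank test on the 2D−3D differences: exact null
  distribution up to 25 non-zero pairs, normal approximation with
  continuity correction above (both knobs configurable; the classic
  convention of dropping zero differences is used and the count
  reported). The six p-values form one Holm family.
* **Variance equality.** Two-sided F-tests comparing the difference
  variances between same-unit DOFs (three translation pairs, three
  rotation pairs; translations never compared to rotations), gated per
  family on Shapiro–Wilk normality at α = 0.05 — if any member fails,
  that family's F-tests are marked invalid and no p-values are emitted.
  Holm correction is applied within each family. Note the gate itself
  has a ≈14% per-family false-trip rate on normal data at n = 3 members.
* **Holm correction.** Step-down with monotonicity enforcement and a
  cap at 1; cross-checked against an independent implementation in the
  tests.
* **Group contrasts** on representative scalar errors (one per
  measurement, patient-labelled): the mean contrast is a linear mixed
  model with a patient random intercept (weekly repeats and missing
  scans handled naturally; fixed effect = group); the 95th-percentile
  contrast is a linear quantile regression at τ = 0.95 whose inference
  comes from a patient-cluster bootstrap (200 replicates, percentile
  CI), because no quantile mixed model is available and the analytic
  quantile-regression covariance assumes independent observations.
  Measured CI coverage on panels with known shifts is 92–96%.

α = 0.05 throughout; configurable.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: each
patient draws a systematic 6-DOF offset ~ N(0, Σ_sys); every fraction's
precorrection error adds an independent random component; a one-time
postcorrection residual ~ N(0, Σ_post); weekly posttreatment errors =
a residual-scale draw plus an intrafractional increment whose SD is
multiplied by m < 1 (default 0.6) for anesthetized or sedated patients;
and one paired planar measurement per designated patient equal to the
volumetric value scaled by (1 − u) (net undercorrection, u = 0.15 by
default) plus measurement noise with a 3× inflated roll component.
All draws come from a single seeded stream: one seed, one byte-identical
cohort CSV.

Defaults are *calibrated, not measured* — chosen once so the pipeline
lands in the percentile bands reported for pediatric cranial image
guidance (95th percentile ≈10 mm before correction, 1–1.5 mm after,
≈2 mm at end of fraction), since per-DOF cohort variances are
unpublished: translational SDs 1.5 mm (systematic) + 2.0 mm (random)
precorrection, 0.35 mm residual, 0.36 mm intrafractional; rotational
SDs 0.5°/0.6° precorrection, 0.2° residual, 0.25° intrafractional;
165 patients, 30 fractions (5/week), 40 paired planar patients,
postcorrection missingness 12%, posttreatment 30%, anesthetized
fraction 77/165 plus 3/165 sedated.

What the generator does **not** emulate: non-Gaussian tails (an
optional contamination knob adds occasional inflated-SD fractions, off
by default), drift over the course, correlations between DOFs,
registration-algorithm bias, or age/anesthesia confounding. Passing
tests therefore demonstrate correctness of the *procedure* under its
stated assumptions, not properties of any clinical dataset.

For contrast-recovery tests a separate scalar-panel generator injects a
pure location shift into per-patient-week representative errors, so the
true mean and every quantile shift by exactly the stated amount — the
only construction in which "recovers 0.40 mm in the 95th percentile"
has an exact ground truth.

## Numerical choices and degenerate inputs

* Rotations are stored in degrees and converted to radians inside the
  geometry module only; exact matrices come from quaternion-based Euler
  composition.
* Unbiased (n−1) variances everywhere; at least 2 patients are required
  to fit, and bootstrap replicates inherit the full record set of each
  resampled patient.
* Zero-variance cohorts yield exactly zero curves with zero-width
  bands; all-zero Wilcoxon differences return p = 1 with a warning;
  mixed-model non-convergence is flagged on the fit rather than raised.
* CSV round trips are bit-exact (floats written as shortest exact
  decimals, read back with round-trip parsing).
* Run manifests record config, seed, library versions and content
  hashes — but no wall-clock timestamp, keeping same-seed runs
  byte-identical.

## Problem sizes used in the checks

The shipped verification uses 10⁶ draws for the analytic chi-3 limit
and for each point of the 5×5 oracle grid, n_sim = 2000 with reduced
bootstrap counts for curve property checks, and 50 replicate cohorts of
165 patients for contrast-recovery coverage — sizes chosen to make the
Monte Carlo error a small fraction of each tolerance.

## Known limitations

* The quantile contrast ignores the random intercept in its point
  estimate (marginal quantile regression); its bootstrap CI accounts
  for clustering, but the estimand is the marginal, not conditional,
  quantile difference.
* The F-tests compare difference columns measured on the same patients
  and are therefore not strictly independent-sample tests; they are
  implemented as specified for comparability.
* The scalarization assumes independent normal per-DOF errors and an
  isotropically oriented target offset; a fixed known offset direction
  is a straightforward extension (the first-order coefficients drop the
  1/3 factor in favour of the actual direction cosines) but is not used
  in the shipped analyses.
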