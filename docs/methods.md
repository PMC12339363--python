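# Methods

This note records the modelling choices behind `vatmap`: what each stage
computes, the defaults and why, what the synthetic generator does and does
not emulate, and the numerical conventions that make results reproducible.

## Coordinate convention

One convention everywhere: world millimetres, RAS+, voxel **centers** as grid
reference points, 0-based indices internally. Voxel index *i* maps to world
`origin + i · voxel_size`; the inverse rounds to the nearest index. TRK's
voxel-order corner convention and TCK's scanner-mm convention are resolved on
read, so all in-memory streamline points are world mm. Volumes are NIfTI-1
with an axis-aligned isotropic affine; oblique, sheared or anisotropic grids
are rejected rather than resampled — this package is defined on isotropic
grids and silently resampling clinical data would hide a real problem.

## VAT model

The activated volume around a contact is a sphere of radius
`r = sqrt(I / 4π σ E)` — the distance at which a point source's field in a
homogeneous medium falls to the activation threshold. Defaults σ = 0.1 S/m,
E = 0.2 V/mm. Units are converted to SI at exactly one point
(`activation_radius`); the public API stays in the clinical units (mA, mm,
V/mm) to avoid silent unit bugs. The model is deliberately minimal: no
tissue anisotropy, no electrode geometry, no pulse-width dependence —
localization uncertainty in this kind of retrospective overlay analysis
dwarfs what a finite-element field model would add. Multiple active contacts
on one lead are reduced to their geometric center.

## Density rendering

* **Visitation densities**: each streamline is resampled at `voxel_size / 2`
  and every sample deposits one count in its containing voxel. The
  deposition rule is plain visitation counting rather than segment-length
  weighting: the downstream activation score is a ratio within one bundle,
  where the constant factor between the two conventions cancels. Total
  unsmoothed mass therefore scales as 1/step; densities are *not* normalized
  across bundles, and activation scores are comparable only within one
  structure across patients.
* **Terminal densities**: only the two endpoints of each streamline deposit
  (unsmoothed mass = 2 × streamline count), rendered at 1 mm and smoothed
  with a 3 mm kernel by default. A "kernel of width 3 mm" is read as
  σ = 3 mm, paralleling the explicit σ = 2 mm of the bundle densities; an
  FWHM reading would be `sigma_mm = 3 / 2.355` and is available by simply
  passing that value.
* **Smoothing**: sampled Gaussian, normalized to unit mass, support 4σ
  (`scipy.ndimage.gaussian_filter`, constant boundary). With 4σ support,
  mass is conserved *exactly* for any input at least 4σ inside the boundary;
  the auto bounding box adds a 3σ + 1-voxel margin around the tractogram
  extent, enough that peak geometry is unaffected while edge mass loss stays
  visible in the logged clip counts rather than silent.
* Reference analyses of this kind use 0.22 mm whole-brain grids; tests and
  the demo run at 0.5–2 mm on small boxes, which changes nothing
  structurally (the operations are resolution-parameterized and the
  brute-force oracles run at the same grid as the implementation).

## Activation scoring and observations

`bundle_activation` is the mean density over all voxels whose centers lie
within the VAT radius (center-in-sphere rule, `≤`); a sphere containing no
voxel center raises a resolution error instead of returning a misleading 0.
Observations pool left and right hemispheres as separate rows, each carrying
the patient's single improvement value. The two hemispheres of one patient
are *not* independent; this pooling is a documented property of the design
the package replicates, not corrected here.

Per-streamline response correlations (for coloring tractograms) use the
fraction of a streamline's 0.5 mm-resampled points inside each site's sphere
as its overlap, correlated with improvement across sites (Pearson). A binary
overlap mode is available. Zero-variance streamlines are reported as NaN —
an explicit undefined marker, never a silent zero.

## Regression and validation

Univariate OLS of improvement on activation (statsmodels); reported: slope,
two-sided slope p from the t statistic with n−2 df, adjusted R². A constant
outcome short-circuits to the null fit (slope 0, p 1, r2_adj = 1−(n−1)/(n−2))
instead of statsmodels' NaN. Leave-one-out refits on each n−1 subset and
normalizes the mean squared prediction error by the *whole-group* outcome
variance — population convention (ddof 0) by default, configurable — so the
same normalizer applies to every fold and `r2_loo = 1 − error` can be
negative. No multiple-testing correction is applied across structures; raw
p-values are reported and must be read accordingly.

## Fingerprints, peaks, conjugations

ROI selection takes streamlines with ≥ 1 point (after 0.5 mm resampling,
robust to sparse polylines) within `diameter / 2` of a coordinate; "2 mm"
ROIs mean diameter 2, radius 1. A group's fingerprint is the terminal
density of the *union* of its per-site selections (a streamline counted
once). Peaks are voxels strictly greater than all 26 neighbors with value ≥
a threshold; nearby peaks are suppressed greedily (larger wins; ties go to
the lexicographically smallest index). Conjugations pair one peak per group
within `pairing_mm` (default 8 mm) that touch the overlap mask — voxels
supra-threshold in both fingerprints at their own `threshold_quantile`
(default 0.95, taken over strictly *positive* voxels: a quantile over all
voxels of a sparse fingerprint collapses to zero). The quantile, pairing
distance and peak separation are free parameters with no canonical values;
all are config keys. Surface projection is trilinear sampling at mesh
vertices (documented ASCII mesh format), zero with a warning outside the
grid.

## Synthetic generator

What it emulates: two bilateral cohorts (n = 12 and n = 14) with baseline
severity ~34.3 ± 4.4 and ~33.4 ± 3.7 on a 0–40 clinician scale and
improvement fractions ~0.44 ± 0.25; spatially disjunct target clusters;
currents ~3 ± 1 mA (truncated > 0; per-patient stimulation currents have no
published reference values, so this default is a flagged free choice);
contact placement jitter of 1.5 mm SD; outcomes linear in a chosen bundle's
activation. Follow-up scores are rounded to integers (clinician scale) and
improvement recomputed from the rounded score; baselines stay continuous and
truncated to [8, 40] by rejection sampling. Improvements are ≤ 1 by
construction (follow-up ≥ 0).

Bundles are smooth streamline families: correlated Gaussian offsets at the
centerline control points (squared-exponential covariance along arclength,
correlation length 2 knot spacings) interpolated with a cubic spline. The
correlation matters: independent knot offsets splined between knots would
deflate the marginal dispersion between knots by up to ~30%; with correlated
knots the pointwise SD stays at `lateral_sd` everywhere, which is what the
dispersion checks assert.

What it does **not** emulate: real bundle geometry (bundles are abstract
lines/curves), registration error, scanner or center effects, non-linear
dose-response, responder/non-responder mixtures, or correlated bilateral
placement. Passing tests therefore demonstrate that the *pipeline* recovers
planted structure under its own assumptions — not that those assumptions
hold in any clinical dataset.

### Demo geometry

The built-in study places the true bundle along y at x = 0 with per-cohort
target clusters on it at y = ±10 and ±20, and the two decoys along x at
y = ±32. Decoy orientation is deliberate: a decoy *parallel* to the true
bundle is a biased null, because its density tail falls monotonically with
the same lateral offset that drives true-bundle activation, making decoy
activation anti-correlated with the true predictor. Running the decoys
orthogonally, displaced beyond the outer clusters, makes their activation
depend on (y, z) offsets while the true bundle's depends on (x, z) — so the
decoys are genuine null structures. A side effect is that the inner cohort's
contacts lie beyond the smoothing support of the decoys, giving
zero-variance decoy activations in that cohort's partition; the screen
reports these as annotated NaN rows rather than failing, which is the
intended behaviour for degenerate per-partition fits.

Effect calibration: slope and noise are set from the realized activation SD
so the patient-level model has R² = 0.5 and the improvement distribution
mean 0.45 / SD 0.25 (`calibrate_effect`). The hemisphere-pooled screen R² is
expectedly lower (~0.1–0.25) since each hemisphere's activation is a noisy
proxy for the bilateral mean.

## Determinism

Every stochastic component takes a seed; the pipeline forks per-stage child
seeds from one root `SeedSequence`. Output tables carry a provenance record
(package version, seed, config hash — the output path is excluded from the
hash) and contain no timestamps, so reruns are byte-identical; this is
asserted by the determinism test.

## Problem sizes

The demo runs 3 bundles × 300 streamlines on a 1 mm grid (~97×113×17
voxels), 26 bilateral patients, 120 synthetic connectome streamlines per
group, and 10–20 replicate reruns for the recovery rates — sizes chosen so
the complete study, including all replicates, recomputes in well under a
minute on one core while keeping every statistic away from degenerate
small-sample corners.

## Known limitations

* The spherical VAT ignores axon orientation and local anisotropy; scores
  inherit that bias.
* Visitation counting makes densities resolution-dependent; only ratios
  within a structure are meaningful.
* Hemisphere pooling double-counts patients; p-values are anti-conservative
  to an unquantified degree.
* Peak/conjugation output depends on free thresholds (quantile, pairing
  distance); they are exposed, not hidden, but results should be reported
  together with their values.
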