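# Methods

This note documents the models, parameters and numerical choices behind
`rehodc`, and what the synthetic validation does and does not show.

## Synthetic cohort model

Each resting-state run is simulated per voxel *v* as

    y_v(t) = 100 + a·g_v(t)·[effect] + b·h(t)·[effect]
             + drift_v·t + M(t)·γ_v + ε_v(t)

* **Noise** ε is AR(1) in time (ρ = 0.3 by default) and spatially
  smoothed to 4 mm FWHM, then scaled to `noise_sd` (default 1, i.e. 1%
  of the 100 baseline). This is the simplest model with the temporal and
  spatial correlation the metrics assume.
* **Local-synchrony effect** *g*: a band-limited (0.01–0.08 Hz) noise
  field smoothed spatially with σ = 1.2 voxels and re-standardized per
  voxel, so *neighbouring* voxels share signal. Adding `a·g` inside the
  ground-truth region raises ReHo there without creating long-range
  coupling.
* **Hub-connectivity effect** *h*: one band-limited time course added to
  every ground-truth voxel, raising each one's correlation to the rest
  of the region and hence its degree centrality.
* **Motion** M(t): six random walks (translations, step SD 0.01 mm;
  rotations, step SD 2·10⁻⁴ rad, stored in radians) coupled into each
  voxel with weights γ_v ~ N(0, 0.2²); a per-voxel linear drift (slope
  SD 0.005/volume) exercises detrending.
* **Effects** are injected only in the (High, post) cell by default,
  with per-subject amplitudes drawn around the configured means
  (between-subject SD = 30% of the mean) so paired tests and the SVM see
  realistic heterogeneity. Default amplitudes a = 1.0, b = 1.2 (in units
  of the noise SD) are calibrated to the qualitative regime the design
  targets — a clearly detectable High effect, nothing in Low or Sham —
  since no raw-signal effect sizes are available to copy.
* **Grid**: 24×24×18 voxels at 3 mm isotropic, TR 2 s, 240 volumes per
  8-min rest run, 120 per 4-min task run, 31 subjects by default. The
  grid is a desk-scale stand-in for a full acquisition matrix so the
  whole pipeline runs in minutes; tests use an even smaller 14×14×10
  grid with 60 volumes and 4–8 subjects, and the acceptance script a
  6-subject cohort on the default grid.
* The **gray-matter mask** is a smooth probability blob (radial falloff
  plus smoothed noise) thresholded at 0.2 and reduced to its largest
  face-connected component — a stand-in for a >20% tissue-probability
  mask. The ground-truth region is an ellipsoid in the right-inferior-
  posterior octant (center (16, 8, 6), radii (3, 3, 2) voxels ≈ 2000 mm³)
  and must lie wholly inside the mask.
* The **task run** alternates 30-s rest/task blocks (rest first); active
  voxels follow a boxcar ⊗ canonical HRF with a Gaussian spatial profile
  (σ = 1.5 voxels) around the target, amplitude 1.5 by default.

What the simulator does **not** emulate: anatomy, physiological
(cardiac/respiratory) noise, scanner drift nonlinearity, registration
error, multi-site effects. Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under its stated
assumptions — not that those assumptions hold in any given real dataset.

## Preprocessing

Fixed order: discard the first 10 volumes → OLS regression of
[intercept, linear trend, 24 motion parameters] → ideal frequency-domain
band-pass 0.01–0.08 Hz. The 24-parameter motion model is
[R(t), R(t−1), R(t)², R(t−1)²] with the lag zero-padded at the first
row. Detrending is folded into the nuisance regression (numerically
identical for OLS residuals to running them as separate steps).
Rank-deficient designs fall back to minimum-norm least squares with a
logged warning — the residual, which is all that propagates, is
unaffected by the degeneracy. The band-pass is an exact boxcar in the
rFFT domain (chosen over an IIR design because its pass/stop behaviour
is exactly testable); the DC component is outside the band, so filtered
series are mean-zero. Spatial smoothing (6 mm FWHM, mask-normalized so
no signal leaks across the mask edge) is applied only to metric maps
after normalization, never to time series.

## Metrics

ReHo uses Kendall's W over the voxel plus its in-mask neighbours
(7 = center + 6 faces by default; 19 and 27 available). Edge voxels use
whatever in-mask members exist (≥ 2) rather than requiring a complete
neighbourhood, which preserves small structures. Ties receive average
ranks with no tie-correction term in the denominator (classical W; ties
have measure zero in floating-point data, and constant series are
logged). DC standardizes each in-mask time course and accumulates the
correlation matrix in row blocks (bounded memory); connections must
*strictly* exceed r = 0.25, negatives are excluded, and zero-variance
voxels contribute nothing. Both maps are divided by their gray-matter
mean (mReHo/mDC, mask-mean exactly 1 before smoothing). Metric maps are
computed on the unsmoothed filtered series; normalization precedes the
6-mm smoothing.

## Task GLM

Canonical double-gamma HRF (gamma shapes 6 and 16, undershoot ratio 1/6,
peak-normalized, zero at t = 0), sampled at the TR. The design holds the
mean-centred convolved boxcar, an intercept, and a discrete-cosine
high-pass basis of floor(2·T/128 s) columns. OLS per voxel; t = β/SE
with df = n − rank. Exact fits are guarded (variance floored at 1e−300)
so the map is never NaN. No pre-whitening is applied; with AR(1) noise
the OLS t values are therefore anticonservative, which is why the null
calibration test uses temporally white noise (the regime in which the
naive GLM is exact). Peak localization returns the maximum-t voxel in
the search mask, ties broken toward the lowest linear index.

## Group statistics

The default ANOVA is repeated measures (subjects are blocks):
F = MS_condition/MS_error with df = (k−1, (k−1)(n−1)) from the two-way
decomposition without replication, matching the within-subject design; a
between-subjects variant is available behind a flag for sensitivity
analysis. Voxels whose error variance is numerically zero (relative
tolerance 1e−12 of the voxel's total variance) are flagged: infinite F
if the condition variance is real, 0 if everything is constant; feature
selection excludes non-finite values.

Image smoothness is estimated from the standardized residual maps of the
ANOVA: the variance λ of spatial first differences of a unit-variance
Gaussian-autocorrelated field gives FWHM = sqrt(4 ln 2/λ) voxels per
axis, floored at one voxel.

Cluster correction follows stationary Gaussian-field theory. The
voxel-forming threshold (p < 0.001 on the F distribution) is mapped to
an equivalent Gaussian height u; with R = V/∏FWHM resels, the expected
cluster count is the 3D Euler-characteristic density
E[m] = R(4 ln 2)^{3/2}(2π)^{−2}(u² − 1)e^{−u²/2}, expected
suprathreshold volume E[N] = V·Φ̄(u), and a cluster of s voxels has
P(n ≥ s) = exp(−β s^{2/3}) with β = (Γ(5/2)·E[m]/E[N])^{2/3}; the
familywise p is 1 − exp(−E[m]·P(n ≥ s)). Clusters are formed by face
(6) connectivity, configurable to 18/26. A within-subject
label-permutation null of the maximum cluster extent is provided as a
nonparametric cross-check; on adequately powered synthetic cohorts the
two select the same clusters, while at very small df (e.g. 5 subjects,
df₂ = 8) the equivalent-Gaussian approximation for an F field is
marginal and borderline clusters can disagree — a known limitation of
GRF inference at low df and smoothness.

Paired t tests are two-tailed; a zero-variance difference is flagged
degenerate (t = 0 if the mean is also 0, signed infinity otherwise).
Bonferroni control divides α by the number of comparisons actually
reported (override available).

## PAIR SVM

Subjects are split ⌊n/2⌋/⌈n/2⌉ into groups A ("X minus Y", label +1)
and B ("Y minus X", label −1). Features are in-mask voxels with
uncorrected ANOVA p < 0.05. The classifier is a linear soft-margin SVM
(C = 1 by default, exposed; no feature standardization — change maps
already share a normalized scale; an SMO-type dual solver at KKT
tolerance 1e−3, verified in tests against an independent quadratic-
programming solution). Validation draws half of each group per
repetition (stratified split-half, 100×), reports mean held-out accuracy
and the arithmetic mean of the signed per-repetition weight vectors,
projected back to a brain map.

Selecting features from the whole-cohort F map before cross-validating
on the same cohort is circular: the selected voxels have, by
construction, consistent condition differences in these subjects, and
even null contrasts then classify far above chance. The pipeline
reproduces this deliberately because it is the published procedure being
emulated (and a test asserts the inflation); `split_half_cv_clean`
recomputes the F map inside every training fold and is the
methodologically safe default for new data. Calibration checks of the
classifier itself therefore use either the clean variant or a fixed
all-mask feature set.

Single-voxel discrimination is an ROC AUC through the Mann–Whitney rank
identity (ties count ½), with the first condition as positive class; on
strong-signal cohorts it is bounded above by the multivariate accuracy.

## Numerical and design choices

* All randomness flows through `numpy` SeedSequences keyed by a master
  seed plus structural indices (subject, condition, phase), so any
  single session is reproducible bit-for-bit without regenerating the
  cohort.
* Voxel indices are 0-based internally; every report table prints world
  mm coordinates through the NIfTI affine (grid centred on the origin).
* Stage outputs carry `provenance.json` sidecars (parameters, package
  version, SHA-256 of outputs); downstream stages verify the hashes of
  what they read and warn on mismatch.
* Statistical calibration tests that rely on independence assumptions
  (KS uniformity of voxelwise p values) run on cohorts simulated without
  spatial smoothing, because smoothing correlates voxels and
  miscalibrates the KS test even when the marginal p values are exactly
  uniform; rate-based checks (binomial CI on the pooled false-positive
  count, familywise cluster rate) run under the full study conditions.
* Null-cohort chance-level accuracy is assessed by averaging split-half
  accuracy over several independent null cohorts: with few subjects the
  per-cohort mean is widely dispersed because every repetition reuses
  the same individuals.

## Known limitations

GRF cluster p values assume a stationary, adequately smooth Gaussian
field and are approximate for F statistics at low df. The task GLM does
not pre-whiten. The simulator's effects are stylized (shared band-
limited signals), so recovered effect sizes have no physical-unit
interpretation; amplitudes are comparable only within the simulation.
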