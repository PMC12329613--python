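# Methods

This note documents the models, numerical choices and limitations of
`ssdelp`: the dose-index arithmetic, the regression conventions used for
conversion-coefficient calibration, the virtual-patient generator that
provides the package's study conditions, and what the synthetic results do
and do not demonstrate about clinical data.

## Dose indices

**Water-equivalent diameter.** For a slice with CT numbers CT(x,y) (HU) and
pixel area *s*² (cm²), the water-equivalent area is accumulated as

    A_w = Σ_ROI (CT/1000 + 1) · s²,      D_w = 2·sqrt(A_w/π).

This is algebraically the mean-CT × area formulation, but the joint
accumulation makes air pixels (−1000 HU) contribute exactly zero. Two ROI
conventions are supported: the default full field of view (valid because of
the air-zero property; the patient table must be masked first on real
images) and a segmented patient contour (threshold −500 HU, largest
connected component, holes filled). On clean images the two agree to
rounding; on noisy backgrounds the contour ROI is preferable because
background noise does not average to exactly zero water-equivalent area.
CT numbers are clamped at −1024 on input. A pathological ROI with negative
total water-equivalent area yields D_w = 0 with a warning instead of an
exception, so batch processing survives degenerate slices.

**SSDE and exam indices.** The size-dependent conversion factor is the
exponential fit f(D_w) = a·exp(−b·D_w) with the 32 cm-reference-phantom
coefficients a = 3.704369, b = 0.03671937 (the abdominopelvic convention;
the pair is a parameter so a different tabulation can be substituted).
SSDE(z) = f(D_w(z))·CTDIvol(z) per slice; the exam mean SSDE is the
unweighted mean over slices. Scan length is n_slices × slice interval — the
imaged length; helical over-ranging is not modelled, so DLP here is the
imaged-length product. SSDE-LP = mean SSDE × scan length. Units are fixed
package-wide: cm, mGy, mGy·cm, mSv, and mSv·mGy⁻¹·cm⁻¹ for conversion
coefficients.

## Calibration

A conversion coefficient is the least-squares slope of reference effective
dose on a dose index, fitted per stratum (male / female / both). Two modes:

* **intercept** (default): ordinary least squares with a free intercept —
  the spreadsheet "simple regression" convention, with the usual centred R².
* **origin**: through-origin least squares; R² is then the uncentered
  coefficient of determination and is labelled as such, because centred and
  uncentered R² are not comparable.

Prediction always applies the slope alone (E = k·index): a conversion
coefficient is by definition a multiplier, and the held-out verification
multiplies the index by k only. This makes intercept-mode fits slightly
biased predictors when the underlying relation is nonlinear (see
"Limitations"), which is a property of the k-factor method itself, not of
the implementation. Through-origin mode is the self-consistent choice when
the dose model is believed proportional; it is also the mode used by the
recovery tests, since the generator's dose model is proportional by
construction and the through-origin estimator has markedly smaller sampling
error on the skewed dose-index distributions (measured ≈0.85% vs ≈1.5%
relative SE at n = 153).

Display rounds slopes to three decimals; all stored and serialized values
keep full precision. A stratum with fewer than two usable records or a
degenerate (constant) index becomes a reported gap, never a silent skip.
The conventional abdominopelvic factor k = 0.015 mSv·mGy⁻¹·cm⁻¹ applied to
DLP is carried as an immutable constant for comparison.

## Validation

Each factor (conventional, fitted DLP, fitted SSDE-LP) is applied to a
held-out cohort; the signed difference predicted − reference is summarized
per stratum as mean ± SD (sample SD, n−1, matching the cohort-description
convention; a single package-wide switch selects population SD). Within a
stratum the stratum's own fitted factor is applied — the both-sexes column
applies the pooled factor to everyone. Factors are ranked by |mean| then SD;
exact ties are reported as tie groups. Underestimation is negative by
construction.

## The virtual cohort generator

The generator emulates a two-year, single-scanner abdominopelvic study:
377 calibration exams (224 male / 153 female) and 293 held-out validation
exams (159 / 134), ages drawn per sex (63 ± 18 male, 60 ± 21 female,
clipped to 18–99). Per exam:

* **Body size**: central water-equivalent diameter from a per-sex normal
  (male 26.5 cm, female 24.5 cm, SD 4.0) truncated at ±2.2 SD and globally
  to 15–38 cm — the scanner's adult abdominal range. A parabolic
  longitudinal taper (8% narrower at the scan ends) gives each exam a
  D_w(z) profile.
* **Scan length**: normal (45 ± 8 cm) clipped to 30–60 cm; slices every
  0.5 cm.
* **Tube-current modulation**: CTDIvol(z) = 10·exp((D_w(z) − 27)/4.5)·exp(η)
  mGy, clipped to 1–80 mGy. The exponential compensates attenuation at a
  fixed image-noise target; η ~ Uniform(±0.5) in the log is a per-exam
  output offset standing in for centering, arm position and phase-to-phase
  variation. The protocol block (120 kV, helical, pitch 0.813, 0.5 s
  rotation, 40 mm collimation, noise setting 15) is carried as metadata
  only.
* **Reference effective dose**:
  E = k_sex · SSDE-LP_true · (1 + ε) · (1 + β·(D̄_w − 27)), with
  k_male = 0.012, k_female = 0.014 mSv·mGy⁻¹·cm⁻¹, multiplicative noise
  ε ~ N(0, 0.05), and β (an optional extra size bias) defaulting to 0.
  Linearity in SSDE-LP makes the true coefficient known exactly, so
  parameter recovery is a sharp test; the high R² the method reports in
  practice justifies a near-proportional surrogate for the Monte-Carlo
  organ-dose engine it replaces, which is out of scope.

Exam indices in cohort generation are computed from the analytic D_w(z)
profile (per-slice f·CTDIvol sums) — exact functionals of the profile.
Rasterization (`render_pixels=True`) draws each slice as a water-density
ellipse of area π(D_w/2)² (AP/LAT ratio 0.75) on an air background at 1 mm
pixels on a 512² grid; round-trip tests confirm the image pipeline
reproduces the generating D_w per slice to ≈0.04% and SSDE-LP to ≈0.005%,
far inside the 1.5% discretization budget, so the analytic and pixel paths
are interchangeable. Slice interiors are uniform 0 HU by default (an
optional texture-noise knob exists); texture does not affect the dose-index
arithmetic under test.

**Why these numbers.** Counts, ages and the protocol mirror the study
shape; body-size means are typical adult abdominal water-equivalent
diameters for a smaller-statured population, which puts the size factor
f > 1 for most patients and makes the conventional 0.015·DLP estimate
underestimate — the regime the method targets. The spread parameters (size
SD and truncation, AEC offset half-width, scan-length SD) and the 5% dose
noise were calibrated once, jointly, so that the sex-stratified SSDE-LP
regressions land in the R² ≈ 0.993–0.996 regime with the lightest
attainable distribution tails: with multiplicative noise, R² > 0.99
requires a wide dose-index spread (CV ≈ 0.8), and heavy lognormal tails
would otherwise dominate the slope's sampling error through leverage
points. Truncated sizes and a bounded log-uniform output offset supply the
spread while capping leverage. With these defaults the through-origin
recovery error is ≈0.8% (1 SE) per sex stratum at the study's sample sizes.
The generator's random draw order (age, scan length, size, AEC offset,
dose noise, exclusion flags) is fixed and independent of rendering, so one
integer seed reproduces cohorts byte-identically on any platform.

**Exclusion flags** default to prevalence 0 — the configured counts are the
retained samples, as cohort tables usually report them — and can be raised
to exercise the filter; flags are annotations, not image artefacts (metal
and arm detection from pixels is out of scope).

## What the synthetic results show — and don't

The generator reproduces the qualitative mechanics of the problem: because
E is proportional to the size-corrected index, the implied per-exam slope
E/DLP equals k·f(D_w) and falls ≈28% from the smallest to the largest size
quartile, so a single DLP regression line cannot fit large patients
(visible as fan-out in the dose-vs-DLP scatter), the DLP fit's R² is lower,
and on held-out data the SSDE-LP factor achieves the smallest discrepancy
SD in every stratum, with the conventional factor underestimating
throughout. These are consequences of the generator's construction — they
demonstrate that the pipeline detects and quantifies the effect correctly,
not that clinical data will show effects of the same magnitude. Real
reference doses are not exactly proportional to SSDE-LP (phantom-matching
steps in the dose engine, protocol mixtures), real size distributions are
not truncated normals, and real DLP-vs-dose relations include scan-range
and contrast-phase structure the generator does not model.

## Numerical and testing notes

* Regressions run through a standard OLS implementation; tests verify the
  slopes against hand-written normal equations to 1e-10 relative, and
  through-origin residual orthogonality (Σx·r = 0) to 1e-9.
* Air-padding invariance and pixel-spacing equivariance of the
  water-equivalent diameter hold to 1e-9 relative on randomized phantoms.
* Statistical acceptance checks aggregate standardized per-seed statistics
  over replicate seeds (e.g. 50) rather than asserting a 2-SE window on a
  single draw, which would reject a correct implementation 5% of the time.
* Discretized-ellipse accuracy: at 0.5 mm test pixels the worst
  closed-form deviation of D_w over clinical sizes is ≈0.02%.
* The cohort CSV writer emits `%.10g` floats, LF line endings, UTF-8;
  write → read → write is byte-identical, which the determinism tests use.
* Problem sizes in the test suite (100-exam round trips, 50-seed replicate
  loops, 200-replicate recovery checks at n = 300) were chosen to give the
  statistical assertions comfortable power while keeping the default suite
  under a minute of compute.

## Limitations

* The conversion-coefficient method itself is linear; the package fits and
  applies it faithfully but does not attempt nonlinear dose models.
* Scan length is imaged length; over-ranging (and hence free-in-air DLP
  contributions) is ignored.
* The DICOM reader is deliberately minimal (rescale, spacing, location,
  per-slice CTDIvol); it is not a dose-report (RDSR) harvester.
* No uncertainty intervals on fitted coefficients beyond R²; no robust or
  weighted regression variants.
* Tissue weighting, organ dosimetry and Monte-Carlo transport are out of
  scope; the reference dose is always an external input (or the surrogate).
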