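# Methods

This note records the models implemented in `retispec`, the defaults and why
they were chosen, and what the synthetic cohorts do and do not emulate. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Synthetic cohort model

The generator emulates an ex-vivo retinal Raman study: two cohorts of
samples (eyes), each measured as a map of spectra. Defaults mirror the study
design the package targets — 39 injured vs 12 control samples, 400 spectra
per sample, one axis from 500 to 3500 cm⁻¹ in 1 cm⁻¹ steps.

**Ratio distribution.** The only published constraints on the 2930/2850
ratio are group medians and IQRs (2.34/0.63 injured, 0.48/0.12 control). We
model the per-sample true ratio as log-normal — positive support and right
skew consistent with a box-plot description — with

- μ = ln(median),
- σ = asinh(IQR / (2·median)) / z₀.₇₅,

an exact closed form (IQR = 2·median·sinh(σ·z₀.₇₅)). Every positive
(median, IQR) pair is feasible; nonpositive inputs raise a solver error.

**Spectral model.** Bands are pseudo-Voigt (mixing 0.5) with FWHM
25 cm⁻¹ in the fingerprint region and 45 cm⁻¹ in the C–H stretch region —
typical condensed-phase Raman widths; positions are the study's feature
bands (1266, 1452, 1660, 2850, 2880, 2930, 2955 cm⁻¹). The injury effect is
carried solely by the 2930-band amplitude. Because neighboring bands leak
intensity into the 2850 and 2930 windows, the generator solves a small
linear equation for the 2930 amplitude so that the *measured peak-height
ratio* (not the raw band amplitude ratio) equals the drawn sample ratio;
without this the windowed ratio would be biased by ~10% at injured-level
ratios. Per-band multiplicative jitter (SD 5%) makes spectra within a
sample vary.

**Baseline, noise, artifacts.** Fluorescence is a low-order polynomial plus
a broad Gaussian centered at 1100 cm⁻¹ (scale 800 cm⁻¹) so the background
decays toward high wavenumber, where the C–H bands sit in the fluorescence
tail. Defaults: baseline amplitude 2.0 (comparable to band heights — the
fingerprint region is fluorescence-dominated, the high-wavenumber region is
not), Gaussian noise SD 0.02 (≈50:1 on a unit band), cosmic rays as
Poisson(0.05/spectrum) spikes 1–3 channels wide and 5–50× the local signal.
All spike positions and true ratios are recorded as ground truth.

**What it does not emulate.** No instrument response or wavelength
calibration error, no detector etaloning or dark current, no spatial
correlation across a map, no within-sample biological heterogeneity beyond
amplitude jitter, and no confounding tissue chemistry. Tests passing on
these cohorts demonstrate the *algorithms* behave correctly at realistic
effect sizes and noise; they do not certify performance on real retinae.

## Preprocessing

Canonical order: cosmic-ray removal → baseline subtraction → normalization →
resampling/cropping.

- **Cosmic rays** ("nearest neighbor method"): each spectrum is compared to
  the median of its two nearest map neighbors (by stage position when
  available, acquisition order otherwise). Channels more than 8 robust SDs
  (1.4826·MAD) *above* the reference are replaced by it. Detection is
  one-sided: spikes are strictly positive detector events, and with only two
  neighbors a symmetric rule lets a spiked neighbor drag clean spectra
  toward the artifact. A within-spectrum running-median fallback
  (`despike_median`) serves single-spectrum inputs.
- **Modified polynomial baseline**: iterative 9th-order fit (Chebyshev basis
  for conditioning); after each fit, points above fit + 1.50·residual-SD are
  excluded and the fit repeated until the baseline changes by < 10⁻⁴
  (relative L2) or 50 iterations (warning + best iterate). The noise
  tolerance 1.50 is interpreted as the residual-SD exclusion multiplier.
- **Spline baseline**: an approximation of proprietary "intelligent spline"
  routines — one knot at the minimum of a smoothed copy of the spectrum in
  each of 11 segments, monotone-safe cubic (PCHIP) through the knots,
  iterated ≤ 20 times with peak regions excluded from knot selection.
- **Normalization**: SNV ((y − mean)/SD) before SOM training; unit-area
  (trapezoidal integral = 1) for cross-instrument comparability. Which is
  applied where is a config choice with SNV the training default.
- **Grids**: linear interpolation onto the integer cm⁻¹ grid strictly inside
  the support (ceil/floor endpoints, no extrapolation), used to align
  spectra with the component library.

## SKiNET

A supervised Kohonen map on a hexagonal grid (offset rows, unit spacing,
row pitch √3/2; grid distance = Euclidean distance between hex centers).
Defaults: 10×10 grid (20×20 supported), 9 epochs, initial learning rate
α₀ = 0.3, initial radius r₀ = ⅔·max(rows, cols), cosine similarity. With
6,400 training spectra the defaults give 57,600 weight updates.

Choices where standard practice had to fill gaps:

- α(t) and r(t) decay **linearly** to (0.01·α₀, 1); the neighborhood kernel
  is a Gaussian of hex-center distance. Both are conventional Kohonen
  schedules and are isolated in the training loop.
- Spectral weights initialize uniformly within the per-channel data range
  (seeded); class weights initialize uniform over classes.
- Supervision: each sample's one-hot class vector is updated by the same
  neighborhood rule as its spectrum, but the BMU search uses spectral
  weights only — class information never influences the topology (tested by
  perturbing class weights and checking BMUs are unchanged).
- Sample order: shuffled epochs when the step budget is ≤ epochs·n;
  sampling with replacement beyond that.
- **SOMDI**: for class c, average cₙ[c]·**w**ₙ over activated neurons whose
  class-weight argmax is c, minus the mean weight of all activated neurons.
  The subtraction is the operational reading of "prominent": it removes the
  shared spectral shape so peaks mark class-specific structure. A class that
  owns no activated neuron yields a zero profile with a warning.
- **Prediction**: BMU's class-weight argmax; a BMU that never activated in
  training defers to the nearest activated neuron on the grid. Ties break
  to the lowest index (neuron and class), documented and deterministic.
- Evaluation: stratified 80/20 split (per class, round(0.2·n) test items),
  stratified 10-fold CV (fold assignment via scikit-learn, seeded), and
  averaging of confusion matrices over independently initialized trainings.

## NNLS decomposition

Per-sample average spectra (baseline-corrected by default) are resampled to
the integer grid, cropped to 1200–3000 cm⁻¹ and fitted against the
four-component library by the Lawson–Hanson active-set solver
(`scipy.optimize.nnls`). Both target and components are unit-area
normalized first so coefficients are comparable across samples (the source
procedure is silent on scaling). Every fit is verified against the KKT
conditions: gradient ≈ 0 on positive coefficients, ≥ 0 on zero ones
(relative tolerance 10⁻⁸). Group comparison uses the pooled two-sample
t-test with a normal-based 95% CI on the mean difference, flagged at
α = 0.05. Without deposited reference spectra the library defaults to the
synthetic component models; user-supplied libraries load through the same
CSV-matrix dialect. Fitting a SOMDI profile instead of an average spectrum
is supported by passing the profile as a spectrum.

## Biomarker statistics

- Peak intensity = windowed maximum (±10 cm⁻¹) of the baseline-corrected
  spectrum; ties take the lower wavenumber. The barcode is the six default
  bands plus R = I(2930)/I(2850); which six bands constitute the barcode is
  configurable (2955 offered as an alternate).
- Quartiles use linear interpolation of order statistics (type 7) — stated
  because IQR-based results change with the convention. Whiskers sit at
  Q1 − 1.5·IQR and Q3 + 1.5·IQR clipped to the data extremes; outliers lie
  strictly beyond.
- ROC: threshold sweep over unique scores; AUC is computed both by
  trapezoidal integration of the curve and as U/(n₊·n₋) with ties credited
  ½, and the call fails if they disagree beyond 10⁻¹⁰ (they are the same
  quantity; the dual computation is a permanent self-check).
- Per-sample (not per-spectrum) ratios feed the box plots and ROC, matching
  a study design whose group sizes are sample counts.

## Determinism and problem sizes

Every stochastic operation is a pure function of (inputs, seed); the
pipeline derives per-stage seeds from the global seed and a stable hash of
the stage name, and its JSON report is byte-identical across runs of one
(config, seed). The test suite runs the expensive checks at reduced scale
chosen to keep the full suite around a minute while preserving the study's
effect sizes: SOMDI band recovery uses 5+5 samples × 50 spectra across 10
seeds; the ratio-AUC check runs the full default cohort (51 samples × 400
spectra) once, measuring ratios on per-sample averages.

## Known limitations

- The SOMDI formula here is one faithful operationalization of a
  qualitatively described procedure; alternative contrasts (e.g. omitting
  the global-mean subtraction) are toggled by editing one expression.
- The spline baseline approximates a proprietary routine and is validated
  only against smooth synthetic backgrounds.
- The reported-scale classification accuracy of ~90% on real porcine data
  is not reproducible from synthetic cohorts: the calibrated group
  separation (2.34 vs 0.48 with small IQRs) is much larger than real
  biological overlap, so synthetic AUCs saturate near 1. Tests therefore
  bound behavior (AUC ≥ 0.95, null ≈ 0.5) rather than match the published
  operating point.
- The generator exposes both "measurements" and "spectra per sample" as
  independent knobs; their relationship in the source design is ambiguous
  and deliberately not resolved here.
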