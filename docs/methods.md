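# Methods

## Forward model

A cell phantom is a sphere (optionally an ellipsoid) with in-plane
centre, radius `R` and integral refractive index `n_cell`, suspended in
buffer of index `n_medium = 1.337`. Its quantitative phase map is the
thin-specimen relation `Δφ(x, y) = (2π/λ)·d(x, y)·(n_cell − n_medium)`
with chord length `d = 2√(max(0, R² − ρ²))` and λ = 0.532 µm. The
off-axis hologram is two-beam interference of the unit-amplitude object
wave `O = exp(iΔφ)` with a tilted plane reference:
`I = |O + R_ref|² = 2 + 2cos(Δφ − 2π f·r)`, where `f` is the carrier
frequency (default (0.3, 0.3) cycles/px). Optional sensor noise is
additive Gaussian on the intensity, clipped at zero. Speckle, coherent
parasitic reflections and aberrations beyond a low-order background are
deliberately not modelled.

Default sampling is 0.1 µm/px on 128×128 frames — the order of
magnitude of a 40× system on a small-pitch CMOS sensor. A lymphocyte
(R ≈ 3.7 µm) then projects to ≈ 73 px diameter, giving the sphere fit
more than 4,000 in-mask pixels; an error is raised when a phantom's
projected radius falls below 3 px, where the fit would be degenerate.

## Reconstruction

Single-shot Fourier demodulation. The frame, mean-subtracted and
apodized with a Tukey window (taper 0.25), is multiplied by the
conjugate reference ramp `exp(+i·2πf·r)`, which moves the +1-order
sideband `exp(iΔφ)` to baseband exactly even when the carrier is not an
integer number of cycles per frame; a Butterworth low-pass (order 6,
radius 45% of the carrier-to-DC distance) isolates it, and the inverse
FFT yields the complex object wave. Without apodization, the
non-periodic carrier leaks DC/conjugate energy through the pass-band
and produces 0.1–0.3 rad edge artifacts; the Tukey taper is a positive
real factor on the object wave, so extracted phase is unaffected
wherever amplitude is usable, and border pixels with negligible
amplitude are zeroed. Auto-detection of the carrier takes the strongest
non-DC spectral peak (parabolic sub-bin refinement, deterministic
half-plane choice) and must agree with the configured carrier within 2
FFT bins.

Phase is the argument of the field, unwrapped with the
reliability-sorting algorithm of scikit-image (a quality-guided
method); our wrapper normalises the global 2π offset so unwrapping is
idempotent and congruent to its input mod 2π. Background: a 2nd-degree
polynomial is fitted to cell-free pixels — below the Otsu threshold of
|phase| with the foreground dilated by 10 px first, because the steep
but sub-threshold skirt of a cell otherwise drags the polynomial and
systematically depresses in-cell phase by ~3% — then subtracted, and
the cell-free median is forced to zero. Cells are optically denser than
buffer, so frames reconstructing predominantly negative are sign-flipped
and flagged.

Numerical refocusing uses the angular-spectrum propagator in the medium
(`k_max = n_medium/λ`); evanescent components are zeroed, so on
band-limited fields — which demodulated fields always are, their
sideband filter being far narrower than the propagating circle — the
propagator is unitary: energy is conserved and `refocus(d)` inverts
`refocus(−d)`. Propagation distances whose transfer-function phase
would alias at the field's effective (99.99%-energy) bandwidth are
rejected. Autofocus minimises the coefficient of variation of the
amplitude over the central half-frame: a pure phase object is flattest
in amplitude at focus.

## Sphere-model fit

Per segmented cell, `(x₀, y₀, R, n_cell)` minimise the sum of squared
phase residuals of the sphere model, by Gauss–Newton with an analytic
Jacobian and Levenberg damping on rejected steps. Initialisation:
mask centroid, `R₀ = √(A/π)`, and
`n₀ = n_medium + λ·φ_peak/(4π·R₀)` from the 99.5th-percentile phase.
The chord-length derivative is singular at ρ = R, so a 2-px boundary
ring is excluded from the residual and the Jacobian denominators are
capped at 0.25·R. Convergence: relative parameter step below 1e-10 or
80 iterations; non-convergent or zero-contrast cells carry a
`fit_failed` flag and NaN parameters. On noiseless rendered phantoms
the fit recovers R and n_cell to < 0.1% and agrees with an exhaustive
grid search over (R, n_cell) to within one grid step (0.01 µm × 1e-4).

Segmentation is hysteresis thresholding: cores above the Otsu threshold
of the positive-phase histogram, grown down to an absolute floor of
0.1 rad. Pure Otsu would erode the projected disk by ~15% in area
because the histogram splits mid-profile; the hysteresis mask tracks
the projected circle to ~1%. Touching cells are never split; a
component with solidity < 0.97 (two overlapping circles form a waist;
single cells, even elongated ones, are convex) is flagged `attached`.

Area and perimeter come from the marching-squares contour of the mask,
with the contour vertices smoothed by a circular 5-point moving average:
the raw 0.5-level contour is a staircase whose length overestimates
smooth perimeters by ~6% (circle FF ≈ 0.89). With smoothing, a
rasterised circle reaches FF = 0.991–0.994, a 100-px square 0.799
(π/4 ≈ 0.785), and 2:1 / 3:1 ellipses match the Ramanujan-perimeter
oracle to < 0.005. FF is clipped to [0, 1]; a pre-clip overshoot beyond
1.02 raises instead of clipping silently.

QC mirrors the study's manual exclusions with declared automated
proxies: FF < 0.65 (deformed cells; platelet–monocyte complexes present
as non-spherical monocytes), fit residual RMS > 0.15 rad, per-cell-type
volume gates, and the `attached` flag. Every exclusion carries a reason
code and kept + excluded partitions the input exactly.

## Cohort simulator

The generator's defaults are the study conditions: 25 patients × 4
timepoints (PreOP, d1, d3, d6) × 2 cell types × 150 cells per sample.
Per-day cohort means/SDs of volume — lymphocytes 208±9 → 218±11 →
210±9 → 210±9 µm³, monocytes 390±25 → 413±20 → 414±27 → 400±23 µm³ —
and the monocyte index course 1.3497 → 1.3485 → 1.3490 → 1.3494 (SD
1×10⁻⁴) are taken as across-patient statistics; the printed ± values
are treated as between-patient SDs of per-patient means (the
alternative SEM reading is documented but not used). Lymphocyte index
day means were set with a smaller (5×10⁻⁵) d1 dip so that, at SD 1×10⁻⁴
across 25 patients, the lymphocyte trend is not significant while the
monocyte drop is — matching the reported significance pattern. Form
factors default to 0.975 with a −0.02 monocyte d1 change. Marker panels
(CD19 absolute/relative, CD86, mHLA-DR, mCD206, necrosis/late
apoptosis, CD3, CD4, platelets) use invented but clinically plausible
scales, since only their correlations with the DHM changes are
constrained.

Correlations are defined on the d1 − PreOP difference scale, as in the
screening table: a latent standard MVN with the configured correlation
matrix (projected to the nearest PSD correlation matrix if needed)
drives all difference variables. Day levels are back-formed so every
configured per-day mean/SD is reproduced: the baseline is drawn with
`cov(X₀, Δ) = (σ₁² − σ₀² − σ_Δ²)/2`, making `var(X₀ + Δ) = σ₁²`; this
requires `|σ₁ − σ₀| ≤ σ_Δ ≤ σ₀ + σ₁`, and the default
`σ_Δ = √((σ₀² + σ₁²)/2)` always satisfies it. Days 3 and 6 revert
toward each patient's baseline deviation with persistence 0.7.

Subgroups reproduce the study's Venn structure exactly at n = 25
(9 complicated course, 8 epinephrine, 7 CRP > 14 mg/dL; overlaps 6, 2
and 0) and scale proportionally with n. Effects enter as mean-centred
offsets on the lymphocyte volume change: complicated/epinephrine
patients have their mean change cancelled (≈ no d1 swelling), high-CRP
patients get +5 µm³. Because these offsets are independent of the
latent copula, they would attenuate the injected correlations of that
variable; its latent correlations are therefore rescaled by
`σ_Δ/s_resid` so the realised total correlation equals the configured
value (verified: −0.504…−0.522 across seeds at n = 10,000 for a target
of −0.514). CRP trajectories are generated so the d1 level defines the
dichotomy exactly; the epinephrine dose column is non-zero only for
treated patients (0.05 + 0.02·latent, clipped), so its configured
difference-scale correlation is realised on the latent scale rather
than exactly in the emitted column.

Within-sample cell-level scatter is not reported and defaults to a 5%
radius CV, with a 1.5× d1 spread multiplier emulating the enlarged d1
standard deviations; per-cell phantom sets emitted for imaging runs are
rescaled so their sample means match the drawn aggregate exactly,
keeping the imaging and aggregates paths comparable.

## Statistics

Per-sample aggregation is the arithmetic mean and ddof-1 SD over
QC-kept cells. Day differences use pairwise-complete deletion with the
dropped-patient count reported. Pearson screening: two-sided p from the
t distribution (n−2 df), results sorted by |r|, stars at 0.05/0.01/
0.001; constant columns are skipped as undefined. The bootstrap draws
10,000 full-size with-replacement resamples; sample p is the fraction
of resample means outside ±0.3·SD of the original mean (for n = 150
standard-normal data the CLT closed form gives ≈ 2.4×10⁻⁴, which the
implementation reproduces), and families of sample p-values are BH
step-up adjusted (statsmodels). A full-size resample omits
(1 − 1/n)ⁿ ≈ 36.7% of distinct entities at n = 150 — implemented and
tested as the expected omitted fraction, resolving the ambiguous
phrasing of that figure. Subgroup contrasts default to Welch's t
(the original test behind the figure stars is unnamed), with a
Mann–Whitney variant switchable; under the null the rejection rate
calibrates to α within Monte-Carlo error.

## Problem sizes and determinism

Default verification sizes: 150-cell samples at 128×128 px for the
imaging chain (a few seconds per sample), 2,000–10,000 patients for
moment and correlation recovery, 10,000 bootstrap resamples and 10,000
null-calibration simulations. All entry points take a seed (NumPy
`default_rng`); fixed seed + config gives byte-identical outputs,
which the pipeline tests assert at the CSV level.

## Known limitations

* No speckle or coherent-noise physics; the noise model is additive
  Gaussian intensity noise plus a polynomial background. Passing tests
  bound algorithmic bias, not robustness to real coherent artifacts.
* The sphere model is also the rendering model, so fit-recovery tests
  demonstrate inverse-problem correctness, not model adequacy for real
  deformed cells; ellipsoid phantoms exist only to exercise QC.
* Marker scales and the within-sample variance split are declared, not
  measured; only the quantities the analysis actually consumes (day
  moments, change-score correlations, subgroup structure) are
  calibrated.
* The epinephrine-dose correlation is realised on the latent scale (see
  above); treat the emitted dose column as a covariate with the right
  qualitative behaviour, not a calibrated marginal.
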