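# Methods

This note documents the models, numerical choices and limitations behind
`petkinfit`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the analysis scripts.

## Problem setting

A reversibly binding brain PET tracer for MAO-B is quantified from a 90-min
dynamic acquisition (29 frames: 10 s × 12, 1 min × 2, 2 min × 1, 4 min × 1,
5 min × 10, 10 min × 3) with serial arterial sampling. The gold-standard
measure is the total distribution volume Vt from compartment modelling
against the metabolite-corrected arterial input; the practical question is
whether static, non-invasive indices (windowed SUV, SUVR−1) can stand in
for it, and which acquisition window and reference region work best. Because
no subject-level dataset is publicly deposited for this tracer, the package
validates its entire chain on synthetic subjects built from published
summary statistics, with known ground truth.

## Arterial input

**Parent fraction.** Plasma radioactivity is total (parent + radiolabelled
metabolites); only the parent drives tissue. The unmetabolized fraction is
modelled by the Watabe function

    f(t) = 1 / (1 + (α t)²)^β,      f(0) = 1, strictly decreasing,

fitted by unweighted least squares on the fraction scale to the sparse HPLC
assay points (≈5, 15, 30, 60, 90 min). Positivity of (α, β) is enforced by
optimizing their logarithms from the start point (0.05 /min, 1.0); noiseless
recovery is better than 1e-4 relative over α ∈ [0.01, 0.2], β ∈ [0.3, 3]
(property-tested). A fitted curve that declines by less than 1e-3 over the
sampled range is flagged non-identifiable rather than trusted. A two-point
calibration helper solves (α, β) exactly through two stated fractions; the
default generator input uses f(30 min) = 0.40, f(90 min) = 0.20, the
published metabolism profile of this tracer class.

**Input function contract.** The corrected curve Cp(tᵢ) = total(tᵢ)·f(tᵢ)
is exposed as a piecewise-linear interpolant: zero before the first sample,
linear between samples, last value held constant afterwards. Linearity is
what makes the compartment convolutions exact (below); the reconstruction
error against the generator's analytic parent curve is ≈1% relative RMS and
is pure interpolation error — the sharp arterial peak between 10-s samples
early, curve curvature across 5-min sample spacing late.

**Open point.** Whether the correction should interpolate f(t) to all sample
times (done here) or interpolate activity to assay times is not determined
by any external constraint; the declared choice is the first.

## Compartment models

1TCM: dCt/dt = K1·Cp − k2·Ct. 2TCM: free+non-specific compartment C1
exchanging with plasma (K1, k2) and with a specifically bound compartment
C2 (k3, k4); Ct = C1 + C2. Measured signal Cm = (1−vB)·Ct + vB·Cb with
fractional blood volume vB.

* **Blood term Cb**: total (uncorrected) plasma by default, with a switch to
  the corrected input. The acquisition protocol described for this tracer
  measures plasma, not whole blood, so total plasma is the closest measured
  surrogate.
* **Solutions**: both models have sums-of-exponentials impulse responses
  (2TCM eigenvalues θ₁,₂ = ((k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4))/2). The
  convolution with the piecewise-linear input is evaluated segment-by-segment
  in closed form — no quadrature grid, the only error is floating point. A
  short series replaces the closed form where θ·Δt < 1e-3 to avoid
  cancellation. The repeated-eigenvalue case (discriminant ≤ 1e-9 relative)
  uses the analytic confluent t·e^{−θt} form, not perturbation. Agreement
  with brute-force stiff ODE integration is ≈1e-7 sup-norm relative across
  the realistic parameter box K1 ∈ [0.05, 0.6], k2 ∈ [0.01, 3],
  k3 ∈ [0, 1.2], k4 ∈ [0.01, 0.12]; the tested contract is 0.1%.
* **Frame sampling**: the model TAC is evaluated at frame mid-times by
  default (the common TAC convention); frame-averaged evaluation (mean of
  the model over each frame on a 0.05-min internal grid) is available and is
  what the synthetic generator uses, since a scanner bins counts over the
  whole frame.
* **Vt**: K1/k2 (1TCM), (K1/k2)(1 + k3/k4) (2TCM); k4 = 0 is the
  irreversible limit and raises rather than returning infinity.

**Fitting.** Weighted nonlinear least squares via
`scipy.optimize.least_squares` (trust-region reflective — LM-equivalent on
these smooth 2–5-parameter problems, and it supports the physical bounds
rates ≥ 0, vB ∈ [0, 0.2]). Defaults: weights wᵢ ∝ frame duration
(count-statistics surrogate; uniform available), starting values K1 = 0.5,
k2 = 0.035, k3 = 0.01, k4 = 0.01, vB fixed at 3% (free mode available),
xtol 1e-8, ftol 1e-10. Noiseless synthetic curves are recovered to machine
precision from these starting values. Uncertainty is the Gauss–Newton
covariance σ²(JᵀWJ)⁻¹ with σ² = wrss/(n−p), reported as %COV =
100·SE/|estimate|; the Vt uncertainty uses the delta method on the full
covariance. A rank-deficient normal matrix yields infinite %COV (flagged,
not fatal). Model criteria: reduced χ² = wrss/(n−p) and
AIC = n·ln(wrss/n) + 2p. These are declared conventions; commercial kinetic
software does not disclose its exact weighting and χ² definitions, so
absolute criterion values are comparable only within this package.

## Logan graphical analysis

x(T) = ∫₀ᵀCp/Ct(T), y(T) = ∫₀ᵀCt/Ct(T); for reversible kinetics y becomes
linear in x with slope Vt. Cumulative integrals use the trapezoid rule on
the union grid of frame mid-times and input knots (exact for the
piecewise-linear input; tissue is taken piecewise linear from Ct(0) = 0).
t\* is the earliest frame mid-time such that an OLS line through all points
at T ≥ t\* leaves every included point within 10% relative deviation of the
fitted line value (the criterion is applied to all included points, and its
denominator is the fitted value — both declared choices). If no start
qualifies, the latest start with ≥ 3 points is used and flagged. The line
fit is plain OLS; the classic noise-induced negative bias of Logan slopes is
therefore present and is asserted only qualitatively under noise. On
noiseless synthetic data the slope matches the closed-form Vt within 2%
(1TCM) and 3% (2TCM, slowest-equilibrating parameter set); the residual
deficit is the finite scan length, and shrinks as t\* moves later
(tested monotonically).

## SUV and SUVR−1

SUV = tissue activity / (injected dose / body weight), density 1 g/mL, so
kBq/mL against MBq and kg reduces to activity·(weight·1000 mL)/(dose·1000
kBq). Windows 30–50, 50–70, 70–90 min tile the late frames exactly;
window means are duration-weighted over whole frames and a window that cuts
a frame is an error (no pro-rating) — the windows were chosen to align with
the schedule, so misalignment indicates a user mistake. SUVR−1 =
SUV_target/SUV_reference − 1 approximates the non-displaceable binding
potential when the reference is (nearly) devoid of specific binding; dose
and weight cancel exactly (tested). Candidate references: cerebral deep
white matter, subcortical white matter, cerebellar cortex, cerebellar white
matter.

## Method comparison

Vt-vs-SUV correlations pool all region × subject points per (method,
window); SUVR−1-vs-density correlations use per-region means over subjects
for the 11 target regions (reference regions excluded from the vector).
Pearson r with two-sided t-distribution p-values, reported at full
precision ("< 0.0001" is a display formatter only). The external region-wise
density vector is user-supplied; the package ships none (the published
autoradiography values are not reprinted anywhere in this repository). The
pipeline excludes compartmental Vt estimates whose %COV exceeds 100% (config
`max_vt_pcov`) from the correlation pooling: such fits — k4 collapsing to
zero and Vt diverging — are non-identifiable by their own error estimate and
carry no information about the underlying volume. They remain in `fit.csv`.

## Synthetic data generator

What it emulates, per subject:

* **Total plasma**: Feng tri-exponential-with-linear-rise,
  Cp(t) = (A1·t − A2 − A3)e^{−λ1 t} + A2e^{−λ2 t} + A3e^{−λ3 t}, defaults
  A1 = 300 kBq/mL/min, A2 = 21, A3 = 20 kBq/mL, λ = (4.0, 0.5, 0.02) /min:
  peak < 2 min, 90-min value < 10% of peak — the "rapid rise, slow washout"
  shape serial sampling shows. Amplitude scales with dose per body volume.
* **Parent fraction**: Watabe calibrated through (30 min, 40%) and
  (90 min, 20%); assay points at 5, 15, 30, 60, 90 min, noiseless (HPLC
  fraction noise is small compared with count noise and is not modelled).
* **Tissue**: 2TCM forward model from the published per-region mean rate
  constants (11 target + 4 reference regions; ground-truth Vt is always
  recomputed from the rates because the published rounded Vt values are not
  consistent with their own rounded rates), true vB = 3%, frame-averaged,
  plus zero-mean Gaussian noise with SD = noise_level·√(mean/duration) per
  frame and negatives clipped. Default noise_level = 0.5, chosen as the
  realistic ROI-level noise scale: at it, the 2TCM %COV pattern
  (microparameters ≈40–50% mean, Vt ≈2–8%) reproduces the magnitude class
  of the published identifiability finding.
* **Cohort**: default 6 subjects; log-normal rate jitter with 10% CV
  (mean-one), dose ~ N(188.4, 32.5²) MBq, weight ~ N(60, 10²) kg (declared,
  not inferred — subject-level dosimetry is not published). One integer
  seed drives everything; regeneration is bit-identical.

What it does **not** emulate: scanner resolution and partial-volume effects,
arterial dispersion/delay, decay-correction errors, whole-blood-vs-plasma
differences, inter-regional noise correlation, head motion. Passing tests
therefore demonstrate the correctness and internal consistency of the
estimators under the stated noise model, not robustness to those
image-space effects.

## Degenerate inputs and tie-breaks

All-zero TAC → Logan raises ("no valid Logan points"); zero input → Logan
slope fit raises on zero x-variance; wrss = 0 → AIC is −∞-like with a
warning; duplicate plasma sample times are averaged before interpolation;
constant parent fractions → non-identifiable flag; fraction outside [0, 1],
overlapping frames, nonpositive dose/weight → validation errors. CSV floats
are read with round-trip precision so write→read is bit-identical.

## Problem sizes

Replicate-based checks use 50 seeded replicates for the identifiability and
model-selection patterns and 25 seeded 3-subject studies for the
window-ordering pattern; the worked cohort is 6 subjects × 15 regions.
These sizes give stable majorities and run comfortably on a laptop.

## Known limitations

* The %COV magnitudes depend on the declared weighting and noise model;
  they reproduce the published *pattern* (macroparameter well identified,
  microparameters not), not its exact values, which would require the
  undeposited subject data.
* Logan Vt inherits OLS attenuation bias under noise.
* The t\* search is O(n²) in frame count (irrelevant at 29 frames).
* The vB term uses total plasma because whole-blood curves are not part of
  the data model; if whole blood were available its shape difference would
  slightly change early-frame fits.
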