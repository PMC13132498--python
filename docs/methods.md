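# Methods notes

## Signal model and analysis assumptions

The pipeline assumes a steady-state paradigm: a grating contrast-reverses at
15 Hz for 3 s per presentation, entraining a phase-locked cortical response
at the reversal frequency. Three analysis assumptions follow:

1. **Exact bin placement.** With 3-s epochs the periodogram grid is
   Δf = 1/3 Hz and 15 Hz is bin 45 exactly (45 integer cycles per epoch), so
   a rectangular window is leakage-free at the response frequency.
   `power_spectrum` warns whenever the configured reversal rate does not sit
   on a bin centre. The periodogram is normalised so that
   `sum(power) == mean(x²)` (Parseval); the SNR is a bin ratio, so the
   normalisation cancels and is fixed purely for testability.
2. **Coherent averaging.** Epochs are averaged in the time domain before the
   FFT. Because the response is phase-locked to stimulus onset, averaging n
   epochs preserves signal power and divides background power by n. All
   epochs enter the average — no artifact rejection — so every eye
   contributes the same segment count.
3. **Local noise estimate.** The noise reference for the 15 Hz bin is the
   mean of the ±2nd and ±3rd neighbouring bins (14, 14.3̄, 15.6̄, 16 Hz);
   the immediate neighbours are excluded to keep any residual leakage or
   slow amplitude modulation out of the noise estimate.

### Known small-sample behaviour of the SNR statistic

After coherent averaging, each background bin is exponentially distributed
(|complex Gaussian|²). The dB statistic is then distributed as
10·log₁₀ of an F(2,8)-like ratio, whose expectation under the null is
(10/ln10)·(ψ(1) − ψ(4) + ln4) ≈ **−1.94 dB**, not 0 dB, with SD ≈ 6.0 dB
(ψ is the digamma function; the unit tests verify the pipeline reproduces
this analytic value). The statistic is nevertheless correctly *centred as a
ratio*: E[numerator]/E[denominator] = 1 under the null, which is the
convention `expected_snr_oracle` uses. Users comparing mean dB-SNR against
a 0 dB threshold should be aware of this negative log-domain bias; it
cancels in group comparisons, which is why the analysis endpoints are
contrasts, fits and areas rather than absolute dB levels.

## Filtering

Band-pass 4–40 Hz, windowed-sinc (Hamming) FIR with −6 dB cutoffs at 3 and
45 Hz; the kernel length is set by a 2 Hz transition band
(≈ 3.3·fs/2 taps, odd), which makes both transitions ≈ 2 Hz wide. The
odd-length linear-phase kernel is applied once by FFT convolution with the
group delay compensated, i.e. zero-phase. Measured response: gain 1.000 at
15 Hz, attenuation > 50 dB at 1 Hz and 50 Hz — comfortably inside the
stated contract (±1 % passband at 15 Hz, ≥ 40 dB at 1 and 50 Hz), which is
the testable surface; the kernel itself is an implementation detail.

## Tuning model

S(f) = G_max − 10·log₁₀2 · (2·(log₂ f − log₂ F_max)/β)².

* A parabola in log₂ spatial frequency; the half-maximum convention is
  defined in *linear* gain, so the curve drops 10·log₁₀2 ≈ 3.01 dB at
  f = F_max·2^(±β/2) and β reads directly as full width at half maximum in
  octaves. (A dB-space half-maximum variant would only rescale β; the
  linear convention is the default and the one all tests pin down.)
* The Gaussian likelihood with a common residual SD makes maximum
  likelihood equivalent to least squares with σ profiled out; `loglik` is
  the profiled value, so refitting with more starts can only increase it.
* Multistart: a stratified grid (log-spaced F_max over its bounds, G_max at
  data quantiles, log-spaced β) with seeded jitter, **plus one
  data-driven closed-form start**: the model is a quadratic in log₂ f, so an
  unconstrained polynomial fit yields the exact unbounded optimum whenever
  its curvature is negative. This start makes small `n_starts` (used inside
  bootstrap and permutation loops) reliable without changing the estimator.
* Bounds: F_max ∈ [0.01, 50] cpd, G_max ∈ [−10, 40] dB, β ∈ [0.05, 20]
  octaves. Peaks may legitimately fall below the 0.5 cpd stimulus floor in
  severe generalized degeneration; such fits are flagged `extrapolated`.
* Group fits pool all eye-level SNR observations of a group; resampling is
  always at the participant level so the two eyes of a drawn participant
  travel together (eyes are not independent).

## Mixed models

Group comparisons and validity associations use a random-intercept model
y = Xβ + u_participant + ε fitted by REML (`ssvepkit._lmm`), with the
variance ratio profiled out in closed form for the single grouping factor.
Wald F tests are type III with Satterthwaite denominator dfs computed from
the exact restricted likelihood (numerical information matrix);
multi-row tests combine per-eigenvector dfs. statsmodels' MixedLM fits the
identical model and is used as an independent cross-check in the tests, not
as the implementation (it provides no Satterthwaite machinery).
Partial η² = F·df₁/(F·df₁ + df₂); marginal R² = fixed-effect variance over
fixed + intercept + residual variance. When the intercept variance is
estimated on the zero boundary the fit is flagged `singular` and inference
falls back to the ordinary fixed-effects ANOVA (which the tests verify it
then equals exactly).

The acuity-validity model regresses logMAR on AUC (slope in logMAR per AUC
unit) — the direction matching the scale of reported slopes (≈ −0.002,
i.e. ≈ 0.3 logMAR per 100 AUC units); the age-confound model regresses AUC
on age in controls. Both directions are available through column choices.

Permutation tests: group-difference tests shuffle participant labels
(Monte-Carlo, default 100 000 replications in the full configuration);
paired run differences use independent sign flips; all report
p = (1 + #extreme)/(reps + 1), a construction that is valid (conservative)
under the null by exchangeability. Extreme-counting uses a 10⁻⁹ relative
slack so permutations that tie the observed statistic in exact arithmetic
are counted despite floating-point rounding. Family-wise error across
contrast families uses Bonferroni–Holm.

## Reliability

* Segment resampling: per eye, epochs are drawn with replacement per
  condition (original counts preserved) and pushed through the production
  averaging → PSD → SNR → curve → AUC path; agreement across the resample
  replicates is ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — with eyes as targets and replicates as raters
  (F-based 95 % CI and p, via pingouin). Note the resample mean is not an
  unbiased estimate of the original AUC: drawing 20-of-20 with replacement
  leaves ≈ 12.6 distinct epochs, inflating residual noise in the average by
  ≈ 1.55× and lowering signal-condition SNR by ≈ 1.9 dB.
* Split half: the full pipeline applied independently to run 1 and run 2
  (10-epoch averages), Pearson-correlated across eyes, with a sign-flip
  permutation paired t test for systematic run differences. The r is
  uncorrected (no Spearman–Brown step-up).

## Synthetic-data generator

What it emulates: three occipital channels at a configurable rate (2048 Hz
default); 1/f^α Gaussian background (α = 1, one-sided density 30 µV²/Hz at
1 Hz per channel) plus a common component (60 µV²/Hz at 1 Hz) shared by all
channels and cancelled exactly by the Laplacian reference; schedules of
seven log-spaced gratings (0.5–13.33 cpd) plus flicker, 20 cycles in two
runs, 3–5 s jittered gaps; phase-locked sinusoidal responses at the
reversal rate added to Oz during stimulation, with amplitude inverted from
the eye's target tuning curve through the closed-form SNR oracle
(signal power A²/2 against per-bin noise 1.5·S(15 Hz)·Δf after the
Laplacian, divided by the scheduled epoch count). Group tuning defaults are
representative fitted values for control (4.20 cpd, 16 dB, 0.80 oct),
macular-dystrophy (0.68, 8.67, 1.71) and generalized-degeneration
(0.08, 3.26, 4.43) profiles; per-participant and per-eye gain effects
(1.5 / 1.0 dB SD) correlate the two eyes; acuity follows
logMAR = 1.73 − 2.15·log₁₀(gain) + N(0, 0.15²), clipped to [−0.3, 2.7],
with entries above 2.1 / 2.5 becoming the categorical "HM" / "PL". Flicker
targets (12 / 10 / 8 dB) keep the 0 cpd endpoint measurable even in the
low-gain profile, mirroring its clinical role. Response phase is fixed at
zero so coherent averaging preserves the signal exactly.

What it does not emulate: volume conduction and realistic topography, eye
movements, blinks and other artifacts, epoch-to-epoch amplitude
fluctuation, line noise inside the analysis band, and non-Gaussian or
non-stationary background. Tuning curves below the noise floor are
truncated to zero amplitude (a −30 dB target is operationally "no
response"). Consequently, passing tests demonstrate the correctness and
calibration of the *analysis* under the stated noise model — not that real
EEG satisfies that model.

One consequence worth stating explicitly: with the default group curves,
4–6 of the 7 grid conditions sit below the noise floor, and a floor-bound
condition contributes an irreducible ≈ 6 dB SD to its SNR estimate. The
trapezoid weights then give within-eye run/resample AUC SDs around 25–37
dB·cpd, so simulated segment-bootstrap ICCs and split-half correlations
level off near 0.3–0.5 for realistic between-eye spread — clearly separated
from pure-noise cohorts (≈ 0) but below what broad, above-floor empirical
curves can reach. Reliability on synthetic cohorts should therefore be read
as a qualitative signal-vs-noise contrast, not a quantitative forecast of
empirical ICCs.

## Problem sizes and numerical choices

* Tests and the acceptance script simulate at 256 Hz — the bin grid,
  filters and statistics are identical to 2048 Hz, and one full eye
  (160 events, ≈ 19 min of signal) processes in ≈ 0.3 s.
* Default resampling sizes in the shipped configurations: 200 bootstrap
  resamples, 199–999 permutation replications, 200 resample replicates for
  ICC; the full-study configuration exposes the 1 000 / 100 000 settings.
* AUC integrates on a linear cpd axis between the extreme sampled
  frequencies with no extrapolation to 0 cpd; a log-axis variant would be a
  configuration switch, and the axis is recorded with the output.
* `snr_db` clamps a machine-zero denominator to float-tiny with a warning
  when the numerator is positive, and raises on an all-zero spectrum.
* EDF export writes EDF+C (16-bit, 1-s records) with markers in a TAL
  annotation channel; physical limits are the exact 8-character header
  values, so encode/decode is self-consistent and round-trips through MNE
  within one quantisation step. Reading supports EDF and 24-bit BioSemi BDF
  through MNE.

## Known limitations

* The mixed-model engine supports a single random intercept (the designs
  used here); no random slopes or crossed factors.
* No harmonic-sum SNR, coherence measures or multi-electrode topographies.
* ICC confidence intervals are F-based; a bootstrap CI variant is not
  provided.
* The acuity link in the generator is a convenient monotone map, not a
  psychophysical model; only its monotonicity and noise level matter for
  the analyses exercised here.
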