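# Methods

## Signal model

The simulator composes the two channels at the pressure level (mmHg):

- **Arterial pulse** — mean pressure plus N sinusoidal harmonics
  `P_a(t) = P_mean + Σ A_n sin(2π f_n t + φ_n)`. Harmonic frequencies must be
  strictly increasing and sampling must strictly exceed twice the highest
  harmonic frequency (rejected otherwise). True per-beat SBP/DBP are the
  continuous extrema of one period (`pulse_extrema`, dense grid + parabolic
  refinement), which is what the pipeline is scored against.
- **Tissue attenuation** — pointwise multiplication by `e^(−α)` with a single
  lumped dimensionless exponent α ≥ 0. The exponent subsumes arterial depth,
  stiffness and density; the package deliberately does not model `e^(−αd)`
  with a separate depth, since depth effects are captured within α once it is
  estimated per subject and contact pressure. Attenuation applies to the full
  signal (DC + AC); amplitude-only attenuation can be explored by constructing
  a pulse with zero mean.
- **Contact pressure** — shared baseline + arbitrary drift function + optional
  raised-cosine motion bumps (onset, duration, amplitude). Drift and motion are
  common to both channels because both transducers ride one strap; channel
  noise is additive Gaussian, drawn independently per channel. The raised
  cosine is a modeling choice for motion transients; nothing downstream depends
  on its exact shape.
- **ADC** — uniform quantizer over a configurable full scale (default 24 bits,
  0–240 mmHg; step 1.43 × 10⁻⁵ mmHg). The electrical chain (bridge excitation,
  gauge factor, PGA) is intentionally not modeled: the artifact works at the
  pressure level, and calibration starts at ADC counts.

All randomness flows through `numpy.random.default_rng(seed)`; there is no
global random state, and identical seeds give bit-identical recordings.

What the generator does *not* emulate: heart-rate variability and beat-shape
change within a recording, respiratory modulation, sensor nonlinearity and
hysteresis, arterial occlusion at high hold-down pressure, and reference-monitor
(volume-clamp) artifacts. Passing tests therefore demonstrate correct inversion
of the stated physics under stationary beats — not robustness to morphology
drift in real subjects.

## Calibration chain

Masses m (grams) on the elliptical transducer face exert
`P = m·g / (π·(a/2)·(b/2)) / 133.3` mmHg (a, b full axis lengths in mm;
conversions internal; 133.3 Pa/mmHg as used in the device's own arithmetic —
not the CODATA 133.322 — so bench worked values reproduce exactly). The face
geometry defaults to 11.89 × 6.7 mm; a directly measured area (62.53 mm², which
differs from the axes-derived 62.57 mm² in the last digit) can override the
computed one. `AdcCalibration` fits counts → mmHg by OLS and reports residual
RMS and slope SE; `daily_check` re-applies check weights against a fitted line
and flags deviations beyond a tolerance (default 0.5 mmHg, an order below
clinically relevant BP error).

## Attenuation model

Per trial, `α = −ln(measured/arterial)` from systolic AC amplitudes — exactly
the inverse of the simulator's attenuation, and estimated from amplitudes
rather than sample-wise ratios because contact-pressure offsets corrupt
pointwise ratios. Across static contact pressures α falls approximately
linearly; `AttenuationRegression` fits `α = m·P_c + b` by OLS on either
trial-level observations or per-pressure group means (both paths exist because
published summaries often expose only means — note that OLS on the five
characterization group means yields intercept 5.60). Prediction is restricted
to a 10–80 mmHg guard band: beyond it the linear trend approaches arterial
occlusion, where the model's assumptions fail, and predictions ≤ 0 are refused.

## Estimation pipeline

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| sample rate | 100 Hz | resolves pulse morphology; keeps fixtures small |
| low-pass | 10 Hz, 4th-order Butterworth, forward–backward | preserves pulse harmonics, removes movement noise, zero phase |
| reference smoothing | 1.0 s centered moving average (odd window) | longer than a beat → suppresses noise, tracks drift; constants pass exactly, making common-mode rejection of shared offsets exact |
| beat band | 40–180 bpm; refractory 0.6/f₀ s | physiologic heart-rate range |
| detection | band-pass 0.6–1.6 f₀ around the Welch spectral fundamental; prominence floor 30% of robust amplitude | un-attenuation multiplies channel noise by e^α (≈ 85–90 at wrist coupling); narrowband timing keeps beat placement stable where broadband peak-picking jitters by large fractions of a cycle |
| beat-time regularization | 9-beat local linear fit | beats are quasi-periodic; first-order Savitzky–Golay removes white timing jitter while reproducing any locally linear beat grid exactly |
| landmark refinement | per-beat affine fit to the ensemble mean-beat template | a peak read from one sample inherits the full e^α-amplified noise; the two-parameter (scale + offset) fit spends every sample of the beat and is exact for identical noiseless beats |
| beat averaging | 5-beat centered mean of landmark series | ≈ 4 s smoothing, standard for wearable BP trend reporting; exact for constant beats |
| BP mapping | affine peak→SBP, foot→DBP; offset-only (unit gain) fallback below 2 distinct amplitudes | realizes reference-calibrated "morphology adjustment" without waveform warping |
| calibration segment | 30 s | the calibration offset's standard error scales as 1/√T; 30 s halves its variance relative to 20 s while leaving an independent evaluation half in a one-minute recording |
| plausibility bounds | SBP 60–260, DBP 30–150 mmHg | estimates outside are flagged `out_of_physiological_range`, never dropped |

The monitor **freezes the mean-beat template at calibration time** and reuses
it during prediction: the template's own noise then shifts calibration and
prediction identically and cancels in the fitted offsets, instead of re-entering
as a per-recording bias.

α for un-attenuation comes either from a fixed value or from the attenuation
model evaluated at the recording's measured contact pressure (mean of the
reference channel). Isolation precedes BP-map fitting. Device and reference
beats are paired by nearest peak time (≤ 1 s); `cross_correlation_lag` exists
for recordings whose clocks need alignment, with manual override by simply
supplying a lag.

Numerical details: zero-phase filtering via `sosfiltfilt` (series must exceed
the pad length); template extrema refined by three-point parabolas; beats whose
template window partially leaves the recording are fitted over the covered
part; a leading beat without a full preceding cycle is discarded (its foot is
unreadable); a constant or pulse-free series yields an empty beat series with a
warning, not an exception.

## Agreement statistics

Sample SDs use the n−1 denominator throughout. "MAE ± SD" is the SD of the
absolute differences. Limits of agreement are bias ± 1.96·SD of the signed
differences — the standard Bland–Altman definition. Pearson r is reported as
NaN with a warning when either series is constant. BHS grades use the
standard's cumulative tiers (A ≥ 60/85/95, B ≥ 50/75/90, C ≥ 40/65/85 % within
5/10/15 mmHg); AAMI passes iff |mean error| ≤ 5 mmHg and SD ≤ 8 mmHg.

## Simulation-study conditions

The cohort harness (`gaugebp.study`) draws subjects with mean arterial pressure
U(85, 110) mmHg, heart rate U(55, 90) bpm, and three harmonics with first-
harmonic amplitude U(16, 24) mmHg and decaying overtones (≈ 40% and 15%,
jittered), worn at 40 mmHg contact with α = 4.44 (the linear model's prediction
at that pressure). Noisy runs use 0.5 mmHg per-channel Gaussian noise and a
shared drift of 1 mmHg/min plus a 2 mmHg, 30 s sway. Recordings are 60 s at
100 Hz with 24-bit quantization; calibration uses the opening 30 s against the
generator's per-beat truth (standing in for a beat-to-beat reference monitor).
Tests run this at 10 subjects per cohort, which completes in seconds while the
pooled beat count (≈ 800) makes cohort MAE stable to ~0.2 mmHg.

## Known limitations

- The affine landmark→BP maps assume a stable pulse morphology between
  calibration and use; morphology change (exercise, vasoactive state) requires
  recalibration, as with all calibrated cuffless devices.
- The template fit assumes one dominant beat shape per recording; arrhythmic
  beats will be fitted poorly (they surface as flagged or outlying estimates,
  not rejections).
- The qualitative impedance product Z = E·ρ·c·d is exposed literally for
  exploration; it is dimensionally nonstandard for a mechanical impedance and
  plays no role in estimation.
- The linear α(P_c) model is valid only within the characterized contact range;
  the guard band enforces this.
- Beat averaging (default 5 beats) trades beat-to-beat bandwidth for noise
  suppression; set `beat_average=1` to study single-beat behavior.
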