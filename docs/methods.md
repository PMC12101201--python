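# Methods

This note documents the models, calibrations and numerical choices behind
`hearthru`, in the spirit of a simulation package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The synthetic head

The head model must express the three cue classes the analysis extracts —
interaural timing, interaural level, and pinna spectral cues — with as few
parameters as possible.  It composes, per direction:

1. **Woodworth interaural delay.**  τ(θ) = (r/c)(θ + sin θ), signed so the
   right ear leads for positive (rightward) azimuth.  The effective radius
   is *derived, not assumed*: inverting τ(90°) = 700 µs gives
   r = c·700 µs/(π/2 + 1) ≈ 9.34 cm, so the ITD span over ±90° matches the
   physiological ±700 µs range by construction.  The delay is applied as a
   pure phase factor (split ±τ/2 across the ears around a 1.5 ms common
   base delay), so the impulse responses carry exact fractional-sample
   timing.
2. **Head shadow.**  A zero-phase per-ear gain of ±(S/2)·sin θ·w(f) dB with
   w(f) = f²/(f² + f_c²), f_c = 1.1 kHz: shadow is negligible at low
   frequencies and saturates above the corner.  S (`shadow_peak`, default
   19 dB) is calibrated so the broadband ILD measured through the package's
   own 3–20 kHz analysis band reaches ≈ ±18.6 dB at ±90°, inside the
   ±(17–20) dB range of a measured dummy head.
3. **Pinna notch.**  One Gaussian dip on the log-frequency axis
   (depth 15 dB, width 0.18 octaves) whose centre moves linearly with
   elevation: 8 kHz + 50 Hz/°, i.e. 6.5–9.5 kHz over ±30°.  Identical on
   both ears, keeping it out of the interaural cues.  The base frequency is
   constrained above 5 kHz so the notch lives in the band transparency
   processing erases.

Because shadow and notch are magnitude-only (zero-phase) and the delay is a
pure phase, the extracted ITD is exactly the Woodworth value and therefore
monotone in azimuth; mirror symmetry ITD(−θ) = −ITD(θ), ILD(−θ) = −ILD(θ)
holds to numerical precision.

`make_hrir_set` accepts a seed for interface uniformity with the stochastic
generators but is fully deterministic — the normal-hearing synthesis has no
random component.

## The transparency transform

Calibrated to measured hear-through behaviour and applied per direction:

- **ILD inflation.**  A signed profile Δ(θ) with two Gaussian lobes
  (8.0 dB at −50°, 7.5 dB at +40°, width 25°) times a smooth odd factor
  tanh(θ/10°) that orients the boost with the natural level difference.
  It is applied as a *flat* interaural gain (±Δ/2 per ear), so the value
  measured by the RMS-band extraction equals the configured profile and
  the residual near the median plane stays within 0–2 dB.
- **ITD jitter.**  A uniform ±20 µs interaural delay perturbation per
  direction.  The 20 µs draw bound is chosen from the extraction
  quantization: at 44.1 kHz the sample-resolution cross-correlation
  quantizes ITDs to 22.68 µs steps, so the *measured* deviation
  (perturbation plus quantization) stays strictly below 45 µs.
- **Spectral flattening.**  Above 5 kHz the magnitude spectrum of each ear
  is replaced by its band RMS level (phase kept).  The replacement is
  energy-preserving per ear, so flattening erases the pinna notch without
  leaking into the measured ILD — the ILD change is carried entirely by
  the boost profile.  An identity parameter set
  (`TransparencyParams.identity()`) disables every component for control
  runs.
- **Processing delay.**  A 1 ms common delay on both ears (latency only;
  no interaural consequence).

## Sweep deconvolution

Excitation is the exponential sweep x(t) = sin(2π f₁ L (e^{t/L} − 1)),
L = T/ln(f₂/f₁), default 15 s from 20 Hz to 20 kHz.  Recovery is performed
in the frequency domain as H = R·X*/(|X|² + ε·max|X|²) with ε = 1e-10 —
Tikhonov-regularised division, equivalent in-band to convolution with an
inverse filter but exact to float precision on noiseless recordings; the
regularisation keeps the out-of-band spectrum (below f₁, above f₂) from
blowing up on noisy input.  The classical time-reversed, e^{−t/L}-weighted
(+6 dB/octave) inverse sweep is also provided (`method="analytic"`), and
its sweep ⊛ inverse pulse is verified to be impulse-like with in-band
sidelobes below −40 dB.

Impulse responses are cropped to 2048 samples (~46 ms, ample for an
anechoic head) around the joint two-ear peak, never before lag zero — the
exponential sweep pushes harmonic-distortion products to negative lags,
which the crop discards.  Both ears use one crop offset, so interaural
timing survives to the sample.

## Cue extraction

- **ITD**: 512-tap linear-phase FIR bandpass 0.1–1.5 kHz applied
  identically to both ears (equal group delay cancels in the
  cross-correlation), half-wave rectification, 1.4 kHz brickwall lowpass
  (literal FFT-bin zeroing; a steep zero-phase Butterworth is selectable),
  then the cross-correlation peak restricted to |lag| ≤ 1 ms — a bound
  that encompasses the ~800 µs physiological limit and caps the estimate
  for any input, including uncorrelated noise.  Ties break toward the
  smallest |lag|.  Sample-resolution peaks by default; parabolic
  sub-sample interpolation sits behind a flag so the default matches the
  sample-quantized delay oracle.
- **ILD**: 4th-order Butterworth bandpass 3–20 kHz (forward-only — level,
  not phase, matters), then 20·log₁₀(RMS_R/RMS_L) over the full cropped
  response.  Zero band energy raises an explicit degenerate-signal error
  rather than returning −∞.
- **Spectral maps**: FFT (length 4096) magnitudes interpolated onto a
  log-spaced 3–16 kHz grid per elevation at 0° azimuth (the median plane —
  the natural choice for elevation cues), optional 1/12-octave smoothing.

Sign conventions everywhere: azimuth positive rightward, elevation
positive up; positive ITD = right ear leads; positive ILD = right ear
louder.

## Rendering and levels

Stimuli are 150 ms bursts band-limited by spectral masking: broadband
0.2–20 kHz, low-pass 0.2–1.5 kHz, high-pass 3–20 kHz, and a harmonic-rich
"buzzer" (150 Hz fundamental, random phases) for localization in noise.
Levels are nominal source levels on a unit-reference dB scale; the SNR of
a rendering is the exact bookkeeping difference target − noise (e.g.
50/60/70 dBA against 55 dBA noise → −5/+5/+15 dB).  The diffuse field uses
eight incoherent white-noise streams from ±30°, ±70°, ±110°, ±150°; the
rear azimuths (±110°, ±150°) have no counterpart on the measured ±90° grid
and fold to the nearest available azimuth, recorded in metadata — a stated
simplification, since rear directions are outside the measurement range.

## Behavioral simulation and metrics

Responses follow the same linear model the analysis fits — response =
bias + gain·target + N(0, σ) per dimension — so parameter recovery is
well-defined.  Default parameters are calibration anchors from summary
localization statistics of normal-hearing adults (azimuth gain 0.97, bias
0.72°; elevation gain 0.93 for broadband/high-pass, 0.17 for low-pass
where pinna cues are absent; degraded device rows with near-zero elevation
gain).  Where the anchor is an MAE under ≈unit gain, the response scatter
is set by the folded-normal identity MAE = σ·√(2/π); where the anchor
mixes systematic and random error (low-pass elevation, device rows) σ is a
coarser judgment call and the rows should be read as "realistic", not
fitted.  Reaction times are 1/promptness with promptness drawn from a
truncated normal (quiet mean 4.77 s⁻¹, in-noise 3.64 s⁻¹; per-trial sd
0.8/0.5 s⁻¹ chosen to give plausibly skewed RT spreads — the anchors are
group means, their dispersion across trials is not published).

Head movements are minimum-jerk reorientations (position profile
10s³ − 15s⁴ + 6s⁵), whose speed peaks at 15/8·amplitude/duration.  The
detector low-passes position at 10 Hz (zero-phase), takes central
differences, combines dimensions as the 2-D speed magnitude, and applies
the 20 °/s criterion with a 50 ms sustained-crossing window; onset is the
first sustained rising crossing, offset the first sustained falling
crossing after it.  Smoothing bandwidth and sustain window are
implementation choices (tracker noise would otherwise trip the criterion);
both are parameters.  Note an interaction worth knowing: for movements
whose speed barely clears threshold, the sustain window requires the
supra-threshold interval to last 50 ms, which biases the detected
flip point upward for short movements (≈ +0.65 °/s at 400 ms duration).
The detection-boundary measurement therefore uses 1 s movements, where the
bias is ≈ +0.1 °/s.

The localization fit is closed-form OLS; r² is the squared Pearson
correlation of target and response (defined as 0 for a constant response,
where the correlation is degenerate); MAE is computed over the same trials.
Pooling concatenates trials before fitting, matching pooled-fit designs.
Confidence intervals on gain/bias are t-based with n − 2 degrees of
freedom.

## Estimation statistics

Contrasts are mean differences with 95% BCa bootstrap intervals
(bias-correction z₀ from the bootstrap distribution, acceleration from
jackknife skewness; computed via `scipy.stats.bootstrap`) and two-sided
permutation p-values on the Welch t statistic with add-one smoothing,
p = (1 + #{|t*| ≥ |t|})/(1 + n_perm) — the standard Monte-Carlo correction
that never returns 0.  When the number of distinct rearrangements is below
the requested count, all are enumerated and the exact count ratio is
returned.  Both default to 5000 resamples.  Because condition contrasts
compare the same listeners, paired mode (bootstrap of within-listener
differences; sign-flipping permutation) is the default; unpaired variants
exist and results carry their mode.

Numerical/degenerate-case policy: zero-variance samples collapse the
interval to the point estimate (flagged) and give p = 1; a point estimate
outside its own BCa interval (pathological, possible in principle) is
flagged rather than silently accepted.

## What the synthetic layer does and does not show

The generators emulate the *structure* of dummy-head acoustics and
listener behavior — cue magnitudes and their azimuth/elevation dependence,
device-induced alterations, linear response mapping, skewed RTs — with
parameters set to published-scale values.  They do not emulate room
acoustics, measurement noise floors, front–back confusions, per-listener
idiosyncrasies, or any device's actual signal path.  Passing tests
therefore demonstrate that the *measurement and analysis chain* is
correct and calibrated (it recovers known ground truth through the full
sweep→deconvolve→extract→fit→contrast path), not that the synthetic
listeners reproduce human data: group-level human results are calibration
anchors here, since their raw data are not deposited.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2048-sample
IRs at 44.1 kHz; ±90° azimuth in 10° steps (19 directions); sweeps of
0.25–1 s in tests (15 s is the measurement default); 1000 random pairs for
the lag-bound stress; 500-trial behavioral blocks with 100 recovery
replicates; 3000 replicates × 1999 resamples for bootstrap coverage and
1000 × 4999 for permutation calibration; 30 bisection iterations at a
120 Hz tracker rate for the detection boundary.  These sizes give
Monte-Carlo errors small against every asserted tolerance.

## Known limitations

- The spherical-head ILD model is smooth and monotone in sin θ; real
  dummy-head ILDs are non-monotonic above ~8 kHz.
- One pinna notch stands in for the full peak/notch complex; elevation
  coding is therefore simpler than reality.
- The ITD extraction is sample-quantized by default (22.7 µs at
  44.1 kHz); sub-sample interpolation exists but is off by default.
- Rear-hemifield noise directions are folded to ±90° rather than
  modelled.
- Behavioral defaults are anchored to group means; trial-level dispersion
  parameters are judgment calls, and no front–back or great-circle error
  analysis is attempted.
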