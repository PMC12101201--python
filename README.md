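# hearthru

Binaural-cue and sound-localization analysis for hearable **transparency
("hear-through") modes** — the feature that re-broadcasts ambient sound
through in-ear speakers via external microphones.

Transparency processing is known to distort the acoustic cues listeners use
to localize sound: interaural time differences (ITD, dominant below
~1.5 kHz), interaural level differences (ILD, dominant above ~3 kHz), and
the pinna's elevation-dependent spectral notches above ~5 kHz.  `hearthru`
implements the complete measurement and analysis chain used to quantify
those effects, exercised end to end on a synthetic-data layer with known
ground truth:

- **Dummy-head acoustics** — a calibrated spherical-head model
  (Woodworth delay τ(θ) = (r/c)(θ + sin θ), first-order head shadow, one
  parametric pinna notch) generating HRIRs over ±90° azimuth × ±30°
  elevation, plus a transparency transform that inflates ILDs off-axis (up
  to 8 dB), jitters ITDs by bounded amounts, and flattens spectra above
  5 kHz.
- **Impulse-response measurement** — exponential sine-sweep excitation
  (15 s, 20 Hz–20 kHz) and inverse-sweep deconvolution.
- **Cue extraction** — ITD via bandpass → half-wave rectification →
  1.4 kHz brickwall → cross-correlation peak (|lag| ≤ 1 ms); ILD via
  3–20 kHz RMS level ratio; spectral maps between 3 and 16 kHz.
- **Localization behavior** — head-movement onset/offset detection by a
  20 °/s velocity criterion, and the linear localization model

      α_R = b_α + g_α · α_T        ε_R = b_ε + g_ε · ε_T

  fitted by least squares (gain *g*, bias *b*, r², and the mean absolute
  error MAE = (1/N)·Σ|response − target|), plus promptness (1/RT, s⁻¹).
- **Estimation statistics** — mean differences with 95% BCa bootstrap
  confidence intervals and permutation t-tests (5000 reshuffles), paired
  by default for within-listener condition contrasts.

## Worked example

```python
import numpy as np
import hearthru as ht

# calibrated normal-hearing HRIRs and their transparency counterpart
nh  = ht.make_hrir_set(elevations=[0.0])
dev = ht.apply_transparency(nh, seed=1)

p_nh, p_dev = ht.cue_profile(nh), ht.cue_profile(dev)
d = np.abs(p_dev.ild_db - p_nh.ild_db)
print("NH ILD span (dB): %.1f .. %.1f" % (p_nh.ild_db.min(), p_nh.ild_db.max()))
print("max ILD inflation: %.2f dB at %g deg" % (d.max(), p_nh.azimuths[np.argmax(d)]))
print("max ITD deviation: %.1f us" % np.abs(p_dev.itd_us - p_nh.itd_us).max())

# simulate a listener and fit the localization regression
model = ht.default_behavioral_model()
rng = np.random.default_rng(0)
targets = np.stack([rng.uniform(-90, 90, 500), rng.uniform(-30, 30, 500)], axis=1)
trials = ht.simulate_trials(model, targets, condition="NH", stimulus="BB", seed=1)
print(ht.fit_localization(trials, "azimuth").summary())
```

Output:

```
NH ILD span (dB): -18.6 .. 18.6
max ILD inflation: 8.02 dB at -50 deg
max ITD deviation: 22.7 us
Localization fit (azimuth), n = 500
  gain g  =   0.9740  (se 0.0074, 95% CI [0.9595, 0.9886])
  bias b  =   0.6432° (se 0.3862, 95% CI [-0.1155, 1.4019])
  r²      =   0.9720
  MAE     =   6.9431°
```

The cue numbers say: the synthetic head spans the physiological ILD range
(±18.6 dB), the transparency transform inflates the ILD by at most 8 dB
(at −50° azimuth, diminishing toward the median plane) while leaving ITDs
within one extraction sample (22.7 µs) of normal.  The behavioral fit
recovers the simulated listener's gain (0.97) and bias (0.72°) inside
their confidence intervals, with an MAE near the σ·√(2/π) value implied
by the response scatter.

The full synthetic study — sweep rendering, deconvolution, cue and
spectral comparison, multi-listener behavioral blocks in quiet and noise,
and paired condition contrasts — runs with one command:

```bash
hearthru run-all --out study_out        # or: hearthru --config my.yaml run-all
```

Subcommands (`simulate-hrir`, `apply-transparency`, `render`,
`deconvolve`, `cues`, `spectra`, `simulate-behavior`, `detect`,
`behavior`, `stats`) expose each stage over the same WAV/CSV formats.

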