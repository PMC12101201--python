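"""Target stimuli, diffuse noise fields, and binaural rendering.

Stimuli are 150 ms Gaussian white-noise bursts band-limited to one of three
ranges — broadband (0.2–20 kHz), low-pass (0.2–1.5 kHz), high-pass
(3–20 kHz) — plus a harmonic-rich broadband "buzzer" used for localization
in background noise.  Band limiting is done by spectral masking, so the
requested band holds essentially all of the signal energy.

Levels are nominal source levels on a dB scale with unit reference
(RMS = 10^(level/20)); the signal-to-noise ratio bookkeeping of a rendering
is exactly ``target_level − noise_level``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .config import NoiseField
from .exceptions import ConfigurationError
from .head_model import HRIRSet

STIMULUS_BANDS = {
    "BB": (200.0, 20000.0),
    "LP": (200.0, 1500.0),
    "HP": (3000.0, 20000.0),
    "buzzer": (200.0, 20000.0),
}

BUZZER_F0 = 150.0  # Hz; harmonic spacing of the buzzer complex


@dataclass
class BinauralRecording:
    """A two-channel recording with its provenance.

    ``snr`` is ``target_level − noise_level`` when noise is present, else
    ``None``.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: int
    source_azimuth: float = 0.0
    source_elevation: float = 0.0
    target_level: float = 60.0
    noise_level: float | None = None
    condition: str = "NH"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.left) != len(self.right):
            raise ConfigurationError("left/right channels must have equal length")

    @property
    def snr(self) -> float | None:
        if self.noise_level is None:
            return None
        return self.target_level - self.noise_level


def _band_limit(x: np.ndarray, sample_rate: float, lo: float, hi: float) -> np.ndarray:
    """Confine a signal's spectrum to [lo, hi] by masking FFT bins."""
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    X[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(X, len(x))


def generate_stimulus(
    kind: str = "BB",
    duration: float = 0.150,
    sample_rate: int = 44100,
    seed: int = 0,
) -> np.ndarray:
    """Generate a band-limited target burst (unit RMS, zero mean).

    ``kind`` is one of ``BB``, ``LP``, ``HP`` (filtered Gaussian noise) or
    ``buzzer`` (a harmonic complex with random phases, 150 Hz fundamental).
    Deterministic given ``seed``.
    """
    if kind not in STIMULUS_BANDS:
        raise ConfigurationError(
            f"unknown stimulus kind {kind!r}; valid kinds: {sorted(STIMULUS_BANDS)}"
        )
    lo, hi = STIMULUS_BANDS[kind]
    hi = min(hi, sample_rate / 2)
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    if kind == "buzzer":
        t = np.arange(n) / sample_rate
        freqs = np.arange(BUZZER_F0, hi, BUZZER_F0)
        phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
        x = np.sum(np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0)
        x = _band_limit(x, sample_rate, lo, hi)
    else:
        x = _band_limit(rng.standard_normal(n), sample_rate, lo, hi)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ConfigurationError("degenerate stimulus: zero energy after band-limiting")
    return x / rms


def _scaled(x: np.ndarray, level_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x * (10 ** (level_db / 20.0) / rms)


def render_recording(
    source: np.ndarray,
    hrir_pair,
    target_level: float = 60.0,
    noise: NoiseField | None = None,
    hrirs_for_noise: HRIRSet | None = None,
    seed: int = 0,
    sample_rate: int = 44100,
    source_azimuth: float = 0.0,
    source_elevation: float = 0.0,
    condition: str = "NH",
) -> BinauralRecording:
    """Render a source through an HRIR pair, optionally in diffuse noise.

    The source is scaled to ``target_level`` and convolved with the
    direction's ``(left, right)`` impulse-response pair.  If a
    :class:`NoiseField` is given, an independent Gaussian white-noise
    stream per noise azimuth is convolved with that direction's HRIR pair;
    per-stream levels are set so the incoherent sum carries
    ``noise.noise_level``.  Noise azimuths beyond the measured ±90° grid
    fold to the nearest available azimuth (recorded in metadata).

    Raises
    ------
    ConfigurationError
        For an empty source, nonpositive levels, or a missing noise HRIR
        set when a noise field is requested.
    """
    source = np.asarray(source, dtype=float)
    if source.size == 0:
        raise ConfigurationError("source signal is empty")
    if target_level <= 0:
        raise ConfigurationError("target_level must be positive (dBA-equivalent)")
    hl, hr = hrir_pair
    src = _scaled(source, target_level)
    left = fftconvolve(src, hl)
    right = fftconvolve(src, hr)

    noise_level = None
    meta: dict = {"seed": seed}
    if noise is not None:
        if hrirs_for_noise is None:
            raise ConfigurationError("a noise field requires hrirs_for_noise")
        noise_level = noise.noise_level
        rng = np.random.default_rng(seed)
        per_stream = noise.noise_level - 10 * np.log10(len(noise.noise_azimuths))
        folds = {}
        el0 = 0.0
        for az in noise.noise_azimuths:
            az_used = hrirs_for_noise.nearest_azimuth(max(-90.0, min(90.0, az)))
            if az_used != az:
                folds[az] = az_used
            nl, nr = hrirs_for_noise.get(az_used, el0)
            stream = _scaled(rng.standard_normal(len(left)), per_stream)
            left = left + fftconvolve(stream, nl)[: len(left)]
            right = right + fftconvolve(stream, nr)[: len(right)]
        if folds:
            meta["noise_azimuth_folds"] = folds

    return BinauralRecording(
        left=left,
        right=right,
        sample_rate=(
            hrirs_for_noise.sample_rate if hrirs_for_noise is not None else sample_rate
        ),
        source_azimuth=source_azimuth,
        source_elevation=source_elevation,
        target_level=target_level,
        noise_level=noise_level,
        condition=condition,
        metadata=meta,
    )
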