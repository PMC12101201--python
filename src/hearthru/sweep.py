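"""Exponential sine-sweep generation and impulse-response recovery.

A logarithmic (exponential) sweep x(t) = sin(2π f1 L (e^{t/L} − 1)) with
L = T / ln(f2/f1) excites each octave with equal energy; convolving the
recorded response with a suitably amplitude-compensated, time-reversed
replica of the sweep collapses the excitation to a band-limited impulse
and pushes harmonic-distortion products to negative lags, where they are
discarded by cropping.

Two recovery routes are provided:

``method="regularized"`` (default)
    Frequency-domain division by the sweep spectrum with Tikhonov
    regularisation, equivalent to convolution with a regularised inverse
    filter but exact to float precision in-band on noiseless recordings.
``method="analytic"``
    Convolution with the classical time-reversed, +6 dB/octave
    amplitude-compensated inverse sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, SampleRateError

DEFAULT_IR_LENGTH = 2048  # ~46 ms at 44.1 kHz, ample for an anechoic head


@dataclass
class Sweep:
    """An exponential sine sweep and its generation parameters."""

    samples: np.ndarray
    sample_rate: int
    f_start: float
    f_end: float
    duration: float

    @property
    def rate_constant(self) -> float:
        """L = T / ln(f2/f1), the exponential time constant in seconds."""
        return self.duration / np.log(self.f_end / self.f_start)

    def instantaneous_frequency(self, t) -> np.ndarray:
        """f(t) = f1 · e^{t/L}."""
        return self.f_start * np.exp(np.asarray(t, dtype=float) / self.rate_constant)


def make_log_sweep(
    f_start: float = 20.0,
    f_end: float = 20000.0,
    duration: float = 15.0,
    sample_rate: int = 44100,
) -> Sweep:
    """Generate a unit-amplitude exponential sweep from f_start to f_end.

    Raises
    ------
    ConfigurationError
        Unless 0 < f_start < f_end <= sample_rate/2 and duration > 0.
    """
    if not (0 < f_start < f_end <= sample_rate / 2):
        raise ConfigurationError(
            f"need 0 < f_start < f_end <= Nyquist; got {f_start}, {f_end} at "
            f"{sample_rate} Hz"
        )
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    L = duration / np.log(f_end / f_start)
    phase = 2 * np.pi * f_start * L * (np.exp(t / L) - 1.0)
    return Sweep(np.sin(phase), sample_rate, f_start, f_end, duration)


def inverse_filter(sweep: Sweep) -> np.ndarray:
    """Time-reversed, amplitude-compensated inverse of an exponential sweep.

    The reversed sweep is modulated by exp(−t/L) — a +6 dB/octave tilt
    with frequency — so that sweep ⊛ inverse approximates a band-limited
    unit impulse within [f_start, f_end].  The output is scaled so the
    mean in-band magnitude of the combined response is unity.

    Note this operation is not an involution: applying it twice does not
    return the original sweep.
    """
    n = len(sweep.samples)
    t = np.arange(n) / sweep.sample_rate
    inv = sweep.samples[::-1] * np.exp(-t / sweep.rate_constant)
    # normalise: unit mean in-band magnitude of sweep * inverse
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfftfreq(nfft, 1.0 / sweep.sample_rate)
    combined = np.fft.rfft(sweep.samples, nfft) * np.fft.rfft(inv, nfft)
    band = (f >= sweep.f_start * 2) & (f <= sweep.f_end / 2)  # interior of band
    scale = np.mean(np.abs(combined[band]))
    if scale == 0:
        raise ConfigurationError("degenerate sweep: zero in-band energy")
    return inv / scale


@dataclass
class ImpulseResponsePair:
    """Left/right impulse responses recovered from one binaural recording.

    ``offset`` is the crop offset in samples, identical for both ears so
    interaural timing is preserved.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: int
    offset: int = 0


def _deconvolve_channels(
    channels, sweep: Sweep, out_length: int, method: str, eps: float
):
    n_rec = len(channels[0])
    n_sw = len(sweep.samples)
    if method == "regularized":
        nfft = 1 << int(np.ceil(np.log2(n_rec + n_sw)))
        X = np.fft.rfft(sweep.samples, nfft)
        denom = np.abs(X) ** 2 + eps * np.max(np.abs(X)) ** 2
        raw = [
            np.fft.irfft(np.fft.rfft(ch, nfft) * np.conj(X) / denom, nfft)
            for ch in channels
        ]
        lag0 = 0
    elif method == "analytic":
        inv = inverse_filter(sweep)
        nfft = 1 << int(np.ceil(np.log2(n_rec + n_sw)))
        I = np.fft.rfft(inv, nfft)
        raw = [np.fft.irfft(np.fft.rfft(ch, nfft) * I, nfft) for ch in channels]
        lag0 = n_sw - 1  # zero lag of the linear convolution
    else:
        raise ConfigurationError(f"unknown deconvolution method {method!r}")

    # locate the main peak jointly across ears; crop both with one offset,
    # never before lag zero (negative lags hold sweep distortion products)
    env = np.sum([np.abs(r) for r in raw], axis=0)
    search = env[lag0 : lag0 + max(out_length * 4, 1)]
    peak = int(np.argmax(search))
    start = lag0 + max(0, peak - out_length // 8)
    cropped = [r[start : start + out_length] for r in raw]
    cropped = [
        np.pad(c, (0, out_length - len(c))) if len(c) < out_length else c
        for c in cropped
    ]
    return cropped, start - lag0


def deconvolve(
    recording,
    sweep: Sweep,
    out_length: int = DEFAULT_IR_LENGTH,
    method: str = "regularized",
    eps: float = 1e-10,
) -> ImpulseResponsePair:
    """Recover a binaural impulse-response pair from a sweep recording.

    Parameters
    ----------
    recording
        Anything with ``left``, ``right`` and ``sample_rate`` attributes
        (e.g. a :class:`~hearthru.stimuli.BinauralRecording`).
    sweep
        The excitation sweep; must share the recording's sample rate.
    out_length
        Crop length in samples around the main peak; both ears are cropped
        with the same offset (recorded on the result) so interaural timing
        survives exactly.
    eps
        Tikhonov regularisation relative to the sweep's peak spectral
        power (``regularized`` method only); keeps the out-of-band
        spectrum from blowing up below f_start / above f_end.
    """
    if recording.sample_rate != sweep.sample_rate:
        raise SampleRateError(
            f"recording at {recording.sample_rate} Hz but sweep at "
            f"{sweep.sample_rate} Hz"
        )
    left = np.asarray(recording.left, dtype=float)
    right = np.asarray(recording.right, dtype=float)
    if len(left) < len(sweep.samples):
        raise ConfigurationError("recording is shorter than the excitation sweep")
    (hl, hr), offset = _deconvolve_channels(
        (left, right), sweep, out_length, method, eps
    )
    return ImpulseResponsePair(hl, hr, sweep.sample_rate, offset)
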