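"""Synthetic dummy-head HRIRs and the transparency-mode transform.

The head model is deliberately minimal — a Woodworth interaural delay, a
first-order head-shadow gain and one elevation-tracking pinna notch — but
each component is calibrated against measured dummy-head behaviour: the
interaural delay spans ±700 µs over ±90° azimuth, the broadband ILD reaches
roughly ±18.5 dB at the lateral poles, and the pinna notch sits above 5 kHz
where hear-through processing erases it.

Impulse responses are synthesised in the frequency domain: a pure phase
delay per ear times a real, zero-phase magnitude (shadow × notch), inverted
by an inverse real FFT.  Magnitude-only shaping leaves the interaural
timing exactly at the Woodworth value, so the extracted ITD is monotone in
azimuth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import HeadModelParams, TransparencyParams
from .exceptions import ConfigurationError, GridRangeError

AZIMUTH_LIMIT = 90.0
ELEVATION_LIMIT = 30.0

DEFAULT_AZIMUTHS = tuple(float(a) for a in range(-90, 91, 10))
DEFAULT_ELEVATIONS = (-30.0, -15.0, 0.0, 15.0, 30.0)


@dataclass
class HRIRSet:
    """Directional binaural impulse responses keyed by (azimuth, elevation).

    ``entries[(az, el)]`` is a ``(left, right)`` pair of equal-length float
    arrays.  ``condition`` labels the measurement condition (e.g. ``"NH"``
    or ``"AirPods"``); ``snr`` the signal-to-noise ratio of the underlying
    recording, if any.  ``metadata`` carries provenance notes such as
    direction folds.
    """

    sample_rate: int
    condition: str = "NH"
    snr: float | None = None
    entries: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def key(self, azimuth: float, elevation: float) -> tuple[float, float]:
        return (float(azimuth), float(elevation))

    def get(self, azimuth: float, elevation: float):
        k = self.key(azimuth, elevation)
        if k not in self.entries:
            raise GridRangeError(
                f"no HRIR at azimuth {azimuth}°, elevation {elevation}°; "
                f"available azimuths {self.azimuths()}, elevations {self.elevations()}"
            )
        return self.entries[k]

    def put(self, azimuth: float, elevation: float, left, right) -> None:
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if left.shape != right.shape:
            raise ConfigurationError("left/right impulse responses must match in length")
        self.entries[self.key(azimuth, elevation)] = (left, right)

    def azimuths(self) -> list[float]:
        return sorted({k[0] for k in self.entries})

    def elevations(self) -> list[float]:
        return sorted({k[1] for k in self.entries})

    def nearest_azimuth(self, azimuth: float) -> float:
        avail = self.azimuths()
        return min(avail, key=lambda a: abs(a - azimuth))


def _check_grid(values, limit: float, what: str) -> np.ndarray:
    values = np.atleast_1d(np.asarray(values, dtype=float))
    bad = values[np.abs(values) > limit]
    if bad.size:
        raise GridRangeError(
            f"{what} {bad.tolist()} outside the supported ±{limit:g}° range"
        )
    return values


def _ear_magnitudes(f: np.ndarray, azimuth: float, elevation: float, p: HeadModelParams):
    """Zero-phase magnitude responses (left, right) for one direction."""
    # head shadow: odd in azimuth, high-pass weighted in frequency
    w = f**2 / (f**2 + p.shadow_corner_freq**2)
    half = 0.5 * p.shadow_peak * np.sin(np.deg2rad(azimuth)) * w  # dB
    # pinna notch: same on both ears, centre tracks elevation
    fc = p.notch_base_freq + p.notch_slope * elevation
    lf = np.log2(np.maximum(f, 1.0) / fc)
    notch = -p.notch_depth * np.exp(-0.5 * (lf / p.notch_width_octaves) ** 2)
    left = 10 ** ((-half + notch) / 20.0)
    right = 10 ** ((+half + notch) / 20.0)
    return left, right


def make_hrir_set(
    params: HeadModelParams | None = None,
    azimuths=DEFAULT_AZIMUTHS,
    elevations=DEFAULT_ELEVATIONS,
    seed: int = 0,
) -> HRIRSet:
    """Synthesise a normal-hearing HRIR set on an (azimuth × elevation) grid.

    Each direction embeds (i) a Woodworth interaural delay
    tau(θ) = (r/c)(θ + sin θ), signed so the right ear leads for positive
    azimuth, (ii) azimuth-dependent high-frequency contralateral
    attenuation, and (iii) an elevation-dependent spectral notch.  The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic generators.

    Raises
    ------
    GridRangeError
        For azimuths beyond ±90° or elevations beyond ±30°.
    """
    p = params or HeadModelParams()
    azimuths = _check_grid(azimuths, AZIMUTH_LIMIT, "azimuth(s)")
    elevations = _check_grid(elevations, ELEVATION_LIMIT, "elevation(s)")

    n = p.ir_length
    f = np.fft.rfftfreq(n, 1.0 / p.sample_rate)
    out = HRIRSet(sample_rate=p.sample_rate, condition="NH", metadata={"seed": seed})
    for el in elevations:
        for az in azimuths:
            tau = p.itd_at(az)
            d_left = p.base_delay + tau / 2.0
            d_right = p.base_delay - tau / 2.0
            mag_l, mag_r = _ear_magnitudes(f, az, el, p)
            hl = np.fft.irfft(mag_l * np.exp(-2j * np.pi * f * d_left), n)
            hr = np.fft.irfft(mag_r * np.exp(-2j * np.pi * f * d_right), n)
            out.put(az, el, hl, hr)
    return out


def _flatten_high_band(h: np.ndarray, sample_rate: float, cutoff: float) -> np.ndarray:
    """Replace the magnitude spectrum above ``cutoff`` with its RMS level.

    Energy above the cutoff is preserved exactly (the flat level is the RMS
    of the replaced band), so flattening erases notches and peaks without
    altering broadband per-ear level — the measured ILD change of the
    transparency transform is then carried entirely by the boost profile.
    Phase is kept, so interaural timing is untouched.
    """
    n = len(h)
    H = np.fft.rfft(h)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    band = f >= cutoff
    if not band.any():
        return h.copy()
    mag = np.abs(H)
    flat = np.sqrt(np.mean(mag[band] ** 2))
    phase = np.angle(H)
    mag = mag.copy()
    mag[band] = flat
    return np.fft.irfft(mag * np.exp(1j * phase), n)


def apply_transparency(
    hrirs: HRIRSet,
    params: TransparencyParams | None = None,
    seed: int = 0,
) -> HRIRSet:
    """Apply a hear-through transform to a normal-hearing HRIR set.

    Per direction: the interaural level difference is inflated by the
    signed Gaussian-lobe profile of ``params`` (applied as a flat
    interaural gain, ±boost/2 per ear); a uniform random interaural delay
    jitter bounded by ``itd_perturbation_bound`` (µs) is drawn per
    direction and split across the ears; the magnitude spectrum above
    ``spectral_flatten_cutoff`` is flattened (elevation-independent); and a
    common ``processing_delay`` (ms) shifts both ears.

    Deterministic given ``seed``.
    """
    params = params or TransparencyParams()
    rng = np.random.default_rng(seed)
    fs = hrirs.sample_rate
    out = HRIRSet(
        sample_rate=fs,
        condition="AirPods",
        snr=hrirs.snr,
        metadata=dict(hrirs.metadata, transparency_seed=seed),
    )
    delay_common = params.processing_delay * 1e-3
    for (az, el), (hl, hr) in sorted(hrirs.entries.items()):
        n = len(hl)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        boost = float(params.boost_profile(az))  # dB, right minus left
        jitter = rng.uniform(-1.0, 1.0) * params.itd_perturbation_bound * 1e-6
        # right leads more for positive jitter: advance right, retard left
        d_l = delay_common + jitter / 2.0
        d_r = delay_common - jitter / 2.0
        gl = 10 ** (-boost / 40.0)
        gr = 10 ** (+boost / 40.0)
        new_l = np.fft.irfft(np.fft.rfft(hl) * gl * np.exp(-2j * np.pi * f * d_l), n)
        new_r = np.fft.irfft(np.fft.rfft(hr) * gr * np.exp(-2j * np.pi * f * d_r), n)
        if params.spectral_flatten:
            new_l = _flatten_high_band(new_l, fs, params.spectral_flatten_cutoff)
            new_r = _flatten_high_band(new_r, fs, params.spectral_flatten_cutoff)
        out.put(az, el, new_l, new_r)
    return out
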