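"""Parameter blocks for the synthetic study and the flat study configuration.

Units follow the field conventions used throughout the package: angles in
degrees (azimuth positive to the listener's right, elevation positive up),
times in the unit named by the field (s, ms or µs), levels in dB / dBA,
frequencies in Hz.  Positive ITD means the sound reaches the right ear first;
positive ILD means the right ear is louder.

All blocks are plain dataclasses that validate their invariants on
construction and round-trip losslessly through YAML (``StudyConfig.save`` /
``StudyConfig.load``); a write→read→write cycle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

#: Speed of sound used for all default calibration, m/s.
SPEED_OF_SOUND = 343.0

#: Interaural delay reached at +90° azimuth by a calibrated head, seconds.
ITD_AT_90 = 700e-6

#: Effective spherical-head radius (m) obtained by inverting the Woodworth
#: delay formula tau(theta) = (r/c)(theta + sin theta) at theta = 90° for a
#: 700 µs delay: r = c * tau / (pi/2 + 1)  (about 9.34 cm).
DEFAULT_EFFECTIVE_RADIUS = SPEED_OF_SOUND * ITD_AT_90 / (math.pi / 2 + 1)

#: Default seed for every stochastic operation (an arbitrary but memorable
#: constant).
DEFAULT_SEED = 20211149


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class HeadModelParams:
    """Spherical-head acoustic model used to synthesise dummy-head HRIRs.

    The model combines a Woodworth interaural delay, a first-order
    high-frequency head-shadow gain, and a single parametric pinna notch
    whose centre frequency moves linearly with source elevation — the
    simplest parameterisation that expresses all three binaural/spectral
    cue classes.

    Parameters
    ----------
    effective_radius : float
        Equivalent sphere radius in metres.  The default is derived, not
        assumed: it inverts the Woodworth formula so the interaural delay
        at ±90° is exactly 700 µs.
    speed_of_sound : float
        m/s.
    shadow_peak : float
        Maximum interaural high-frequency level difference (dB) produced by
        head shadow at ±90°, split symmetrically between the two ears.
        Calibrated so the broadband ILD measured through the 3–20 kHz
        analysis band at ±90° lands in the ±(17–20) dB range.
    shadow_corner_freq : float
        Corner frequency (Hz) of the shadow's high-pass weighting
        f² / (f² + fc²): shadow is negligible well below it and saturates
        above it.
    notch_base_freq : float
        Pinna-notch centre frequency (Hz) at 0° elevation.  Must exceed
        5 kHz — the notch has to live in the band a transparency device
        erases.
    notch_slope : float
        Notch-centre shift per degree of elevation (Hz/°).
    notch_depth : float
        Notch depth in dB.
    notch_width_octaves : float
        Gaussian half-width of the notch on a log-frequency axis, octaves.
    sample_rate : int
        Hz.
    ir_length : int
        Impulse-response length in samples.
    base_delay : float
        Common acoustic propagation delay (s) applied to both ears, keeping
        the fractional-delay kernels causal inside the IR buffer.
    """

    effective_radius: float = DEFAULT_EFFECTIVE_RADIUS
    speed_of_sound: float = SPEED_OF_SOUND
    shadow_peak: float = 19.0
    shadow_corner_freq: float = 1100.0
    notch_base_freq: float = 8000.0
    notch_slope: float = 50.0
    notch_depth: float = 15.0
    notch_width_octaves: float = 0.18
    sample_rate: int = 44100
    ir_length: int = 2048
    base_delay: float = 1.5e-3

    def __post_init__(self) -> None:
        _require(self.effective_radius > 0, "effective_radius must be > 0")
        _require(self.speed_of_sound > 0, "speed_of_sound must be > 0")
        _require(
            self.notch_base_freq > 5000.0,
            "notch_base_freq must exceed 5000 Hz (the pinna notch must sit in "
            "the band that transparency processing flattens)",
        )
        _require(self.sample_rate > 0, "sample_rate must be > 0")
        _require(self.ir_length > 0, "ir_length must be > 0")

    def itd_at(self, azimuth_deg: float) -> float:
        """Woodworth interaural delay (s) at an azimuth; positive = right leads."""
        th = math.radians(azimuth_deg)
        return (self.effective_radius / self.speed_of_sound) * (th + math.sin(th))


@dataclass
class TransparencyParams:
    """Cue alterations applied by a hear-through ('transparency') transform.

    Calibrated to the measured device behaviour: ILD inflated off-axis with
    asymmetric maxima (8.0 dB near −50°, 7.5 dB near +40°), a sub-2 dB
    residual near the median plane, ITDs preserved to well under 45 µs, and
    the magnitude spectrum flattened above 5 kHz (erasing pinna notches).

    ``ild_boost_*`` fields describe the primary Gaussian lobe of the ILD
    inflation profile; ``secondary_boost_*`` the weaker lobe on the other
    side.  The inflation magnitude is signed by a smooth odd function of
    azimuth (width ``sign_transition_width``) so the boost always amplifies
    the natural level difference.

    ``itd_perturbation_bound`` (µs) bounds the uniform random interaural
    delay jitter per direction; it must stay below 45 µs.
    ``processing_delay`` (ms) is a common delay added to both ears.
    """

    ild_boost_peak: float = 8.0
    ild_boost_azimuth: float = -50.0
    ild_boost_width: float = 25.0
    secondary_boost_peak: float = 7.5
    secondary_boost_azimuth: float = 40.0
    sign_transition_width: float = 10.0
    median_residual_band: list[float] = field(default_factory=lambda: [0.0, 2.0])
    spectral_flatten_cutoff: float = 5000.0
    spectral_flatten: bool = True
    itd_perturbation_bound: float = 20.0
    processing_delay: float = 1.0

    def __post_init__(self) -> None:
        _require(self.ild_boost_peak >= 0, "ild_boost_peak must be >= 0")
        _require(self.secondary_boost_peak >= 0, "secondary_boost_peak must be >= 0")
        _require(self.ild_boost_width > 0, "ild_boost_width must be > 0")
        _require(
            self.itd_perturbation_bound < 45.0,
            "itd_perturbation_bound must stay below 45 µs",
        )
        _require(self.itd_perturbation_bound >= 0, "itd_perturbation_bound must be >= 0")
        _require(
            self.spectral_flatten_cutoff >= 5000.0,
            "spectral_flatten_cutoff must be >= 5000 Hz",
        )
        _require(self.processing_delay >= 0, "processing_delay must be >= 0")

    @classmethod
    def identity(cls) -> "TransparencyParams":
        """A transform that changes nothing (useful as a control)."""
        return cls(
            ild_boost_peak=0.0,
            secondary_boost_peak=0.0,
            itd_perturbation_bound=0.0,
            spectral_flatten=False,
            processing_delay=0.0,
        )

    def boost_profile(self, azimuth_deg) -> "float":
        """Signed ILD inflation (dB) applied at an azimuth.

        Positive values make the right ear relatively louder.  The two
        Gaussian lobes give the inflation magnitude; the smooth odd sign
        factor orients it with the natural level difference (right louder
        for positive azimuth).
        """
        import numpy as np

        az = np.asarray(azimuth_deg, dtype=float)
        mag = self.ild_boost_peak * np.exp(
            -(((az - self.ild_boost_azimuth) / self.ild_boost_width) ** 2)
        ) + self.secondary_boost_peak * np.exp(
            -(((az - self.secondary_boost_azimuth) / self.ild_boost_width) ** 2)
        )
        return mag * np.tanh(az / self.sign_transition_width)


@dataclass
class NoiseField:
    """Diffuse background-noise configuration.

    Eight incoherent Gaussian white-noise streams from fixed azimuths at a
    total level of 55 dBA, with the target following the noise onset by a
    randomised 200–300 ms lead.
    """

    noise_azimuths: list[float] = field(
        default_factory=lambda: [-150.0, -110.0, -70.0, -30.0, 30.0, 70.0, 110.0, 150.0]
    )
    noise_level: float = 55.0
    onset_lead: list[float] = field(default_factory=lambda: [200.0, 300.0])

    def __post_init__(self) -> None:
        _require(self.noise_level > 0, "noise_level must be > 0")
        _require(
            all(-180.0 <= a <= 180.0 for a in self.noise_azimuths),
            "noise azimuths must lie within ±180°",
        )
        _require(
            len(self.onset_lead) == 2 and 0 <= self.onset_lead[0] <= self.onset_lead[1],
            "onset_lead must be a (low, high) ms pair",
        )


@dataclass
class TrajectoryParams:
    """Synthetic head-orientation trajectory: a minimum-jerk reorientation.

    Angles in degrees, times in ms, tracker rate in Hz, position noise in
    degrees (per-sample, Gaussian).
    """

    start_azimuth: float = 0.0
    start_elevation: float = 0.0
    end_azimuth: float = 40.0
    end_elevation: float = 0.0
    movement_latency: float = 300.0
    movement_duration: float = 400.0
    tracker_rate: float = 120.0
    noise_sd: float = 0.0
    trial_duration: float = 2000.0

    def __post_init__(self) -> None:
        _require(self.movement_duration > 0, "movement_duration must be > 0")
        _require(self.tracker_rate > 0, "tracker_rate must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(
            self.trial_duration >= self.movement_latency + self.movement_duration,
            "trial_duration must cover latency + movement",
        )


@dataclass
class ResponseParams:
    """Linear target→response model for one condition/stimulus/dimension.

    response = bias + gain · target + N(0, response_sd);
    reaction time = 1 / promptness, promptness ~ N(mean, sd) truncated > 0.
    """

    gain: float = 1.0
    bias: float = 0.0
    response_sd: float = 0.0
    promptness_mean: float = 4.0
    promptness_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(self.response_sd >= 0, "response_sd must be >= 0")
        _require(self.promptness_mean > 0, "promptness_mean must be > 0")
        _require(self.promptness_sd >= 0, "promptness_sd must be >= 0")


# sigma = MAE * sqrt(pi/2) converts a mean-absolute-error anchor into the
# Gaussian response scatter that produces it when gain≈1 and bias≈0.
_MAE_TO_SD = math.sqrt(math.pi / 2)


def default_behavioral_model() -> "BehavioralModel":
    """Behavioral simulator calibrated to summary localization statistics.

    Keys are (condition, stimulus, dimension) with ``"*"`` wildcards.
    Normal-hearing rows use published-quality localization (azimuth gain
    0.97, bias 0.72°, scatter giving MAE ≈ 6.8°); the transparency-device
    rows use degraded elevation mapping (gain near 0) and inflated scatter.
    Promptness is ≈4.77 s⁻¹ in quiet, ≈3.64 s⁻¹ in noise.
    """
    q, n = 4.77, 3.64  # promptness means, quiet / in noise (s^-1)
    tbl = {
        ("NH", "*", "azimuth"): ResponseParams(0.97, 0.72, 6.81 * _MAE_TO_SD, q, 0.8),
        ("NH", "LP", "elevation"): ResponseParams(0.17, 1.42, 12.0, q, 0.8),
        ("NH", "*", "elevation"): ResponseParams(0.93, 1.42, 6.79 * _MAE_TO_SD, q, 0.8),
        ("AirPods", "*", "azimuth"): ResponseParams(0.90, 0.5, 19.6 * _MAE_TO_SD, q, 0.8),
        ("AirPods", "*", "elevation"): ResponseParams(0.05, 7.9, 15.0, q, 0.8),
        ("NH", "buzzer", "azimuth"): ResponseParams(0.99, 0.13, 7.58 * _MAE_TO_SD, n, 0.5),
        ("NH", "buzzer", "elevation"): ResponseParams(0.80, 1.0, 9.0 * _MAE_TO_SD, n, 0.5),
        ("AirPods", "buzzer", "azimuth"): ResponseParams(0.85, 0.5, 19.6 * _MAE_TO_SD, n, 0.5),
        ("AirPods", "buzzer", "elevation"): ResponseParams(-0.02, 7.9, 16.0, n, 0.5),
    }
    return BehavioralModel(tbl)


@dataclass
class BehavioralModel:
    """Table of :class:`ResponseParams` keyed by (condition, stimulus, dimension).

    Lookup tries the exact key first, then wildcard stimulus, then wildcard
    condition+stimulus.
    """

    table: dict = field(default_factory=lambda: default_behavioral_model().table)

    def params_for(self, condition: str, stimulus: str, dimension: str) -> ResponseParams:
        for key in (
            (condition, stimulus, dimension),
            (condition, "*", dimension),
            ("*", "*", dimension),
        ):
            if key in self.table:
                return self.table[key]
        raise ConfigurationError(
            f"no behavioral parameters for ({condition}, {stimulus}, {dimension})"
        )


@dataclass
class SweepParams:
    """Exponential sine-sweep excitation: 15 s, 20 Hz – 20 kHz."""

    f_start: float = 20.0
    f_end: float = 20000.0
    duration: float = 15.0


@dataclass
class StudyConfig:
    """One flat configuration governing the whole synthetic study.

    Cross-stage calibration constants (head model, transparency transform,
    grids, levels) live together here because downstream measurements
    depend on their joint values.
    """

    head: HeadModelParams = field(default_factory=HeadModelParams)
    transparency: TransparencyParams = field(default_factory=TransparencyParams)
    noise: NoiseField = field(default_factory=NoiseField)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    sweep: SweepParams = field(default_factory=SweepParams)
    behavior: BehavioralModel = field(default_factory=default_behavioral_model)
    azimuths: list[float] = field(default_factory=lambda: [float(a) for a in range(-90, 91, 10)])
    elevations: list[float] = field(default_factory=lambda: [-30.0, -15.0, 0.0, 15.0, 30.0])
    target_levels: list[float] = field(default_factory=lambda: [50.0, 60.0, 70.0])
    n_listeners: int = 10
    n_trials_per_block: int = 40
    seed: int = DEFAULT_SEED
    output_dir: str = "hearthru_out"

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # BehavioralModel's tuple keys are not YAML-safe; flatten them.
        d["behavior"] = {
            "|".join(k): dataclasses.asdict(v) for k, v in self.behavior.table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        behav = BehavioralModel(
            {tuple(k.split("|")): ResponseParams(**v) for k, v in d.pop("behavior").items()}
        )
        return cls(
            head=HeadModelParams(**d.pop("head")),
            transparency=TransparencyParams(**d.pop("transparency")),
            noise=NoiseField(**d.pop("noise")),
            trajectory=TrajectoryParams(**d.pop("trajectory")),
            sweep=SweepParams(**d.pop("sweep")),
            behavior=behav,
            **d,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
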