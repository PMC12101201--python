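"""Localization behavior metrics: movement detection, target–response
regression, mean absolute error, and promptness.

The central object is :class:`LocalizationModel`, a small linear model of
the response angle as a function of the target angle,

    response = bias + gain · target,

fitted by ordinary least squares separately for azimuth and elevation.
A perfect localizer has gain 1, bias 0° and coefficient of determination
1.0.  :meth:`LocalizationModel.fit` returns a
:class:`LocalizationResults` carrying the estimates, their standard
errors, confidence intervals, r², the mean absolute error over the same
trials, and a ``summary()`` table.

Reaction times are summarised as promptness (1/RT in s⁻¹), which
normalises the positively skewed RT distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import ConfigurationError, DegenerateSignalError

DIMENSIONS = ("azimuth", "elevation")

#: Angular-speed criterion separating head movement from rest, °/s.
VELOCITY_THRESHOLD = 20.0


@dataclass
class Trajectory:
    """A head-orientation time series sampled at ``tracker_rate`` Hz."""

    time: np.ndarray
    azimuth: np.ndarray
    elevation: np.ndarray
    tracker_rate: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if not (len(self.time) == len(self.azimuth) == len(self.elevation)):
            raise ConfigurationError("trajectory series must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ConfigurationError("trajectory time must be strictly increasing")


@dataclass
class Trial:
    """One localization response."""

    listener_id: str = "L01"
    condition: str = "NH"
    stimulus: str = "BB"
    level: float = 60.0
    snr: float | None = None
    target_azimuth: float = 0.0
    target_elevation: float = 0.0
    response_azimuth: float = 0.0
    response_elevation: float = 0.0
    reaction_time: float | None = None  # ms

    def __post_init__(self):
        if abs(self.target_azimuth) > 90 or abs(self.target_elevation) > 30:
            raise ConfigurationError(
                "targets must lie within ±90° azimuth and ±30° elevation"
            )
        if self.reaction_time is not None and self.reaction_time <= 0:
            raise ConfigurationError("reaction_time must be positive (ms)")

    def target(self, dimension: str) -> float:
        return self.target_azimuth if dimension == "azimuth" else self.target_elevation

    def response(self, dimension: str) -> float:
        return (
            self.response_azimuth if dimension == "azimuth" else self.response_elevation
        )


@dataclass
class MovementEvent:
    """Detected head movement: onset/offset times and final orientation."""

    onset: float  # s
    offset: float  # s
    final_azimuth: float
    final_elevation: float
    reaction_time: float  # ms, onset relative to stimulus onset
    offset_truncated: bool = False


def detect_movement(
    traj: Trajectory,
    threshold: float = VELOCITY_THRESHOLD,
    stimulus_onset: float = 0.0,
    smooth_hz: float = 10.0,
    sustain: float = 0.05,
) -> MovementEvent | None:
    """Find movement onset and offset by a velocity-threshold criterion.

    Angular speed is the magnitude of the 2-D (azimuth, elevation)
    velocity vector, computed by central differences after zero-phase
    10 Hz low-pass smoothing of position (tracker noise would otherwise
    trip the threshold spuriously).  Onset is the first sample from which
    speed stays above ``threshold`` for the ``sustain`` window; offset is
    the first later sample from which it stays below for the same window
    (falling-crossing reading).  Returns ``None`` — the no-movement flag —
    if the speed never sustains above threshold.

    The detection is invariant to constant offsets of the whole
    trajectory.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    fs = traj.tracker_rate
    az, el = traj.azimuth, traj.elevation
    if len(az) >= 13 and smooth_hz < fs / 2:
        sos = signal.butter(2, smooth_hz, fs=fs, output="sos")
        az = signal.sosfiltfilt(sos, az)
        el = signal.sosfiltfilt(sos, el)
    vaz = np.gradient(az) * fs
    vel = np.gradient(el) * fs
    speed = np.hypot(vaz, vel)

    w = max(1, int(round(sustain * fs)))
    above = speed > threshold
    run_above = np.convolve(above.astype(int), np.ones(w, dtype=int), mode="valid")
    starts = np.flatnonzero(run_above == w)
    if starts.size == 0:
        return None
    onset_i = int(starts[0])

    below = ~above
    run_below = np.convolve(below.astype(int), np.ones(w, dtype=int), mode="valid")
    cand = np.flatnonzero(run_below == w)
    cand = cand[cand > onset_i]
    truncated = cand.size == 0
    offset_i = len(speed) - 1 if truncated else int(cand[0])

    onset_t = float(traj.time[onset_i])
    return MovementEvent(
        onset=onset_t,
        offset=float(traj.time[offset_i]),
        final_azimuth=float(traj.azimuth[offset_i]),
        final_elevation=float(traj.elevation[offset_i]),
        reaction_time=(onset_t - stimulus_onset) * 1000.0,
        offset_truncated=truncated,
    )


def promptness(reaction_time_ms: float) -> float:
    """Reciprocal reaction time, 1000/RT_ms, in s⁻¹."""
    if reaction_time_ms <= 0:
        raise ConfigurationError("reaction time must be positive")
    return 1000.0 / reaction_time_ms


def mean_absolute_error(trials, dimension: str) -> float:
    """Mean absolute target–response error (degrees) across trials."""
    _check_dimension(dimension)
    if len(trials) == 0:
        raise ConfigurationError("mean_absolute_error needs at least one trial")
    errs = [abs(t.response(dimension) - t.target(dimension)) for t in trials]
    return float(np.mean(errs))


def _check_dimension(dimension: str) -> None:
    if dimension not in DIMENSIONS:
        raise ConfigurationError(f"dimension must be one of {DIMENSIONS}")


class LocalizationModel:
    """OLS model of response angle on target angle for one dimension.

    Parameters
    ----------
    targets, responses : array-like
        Paired angles in degrees.
    dimension : str
        ``"azimuth"`` or ``"elevation"`` (a label carried into results).
    """

    def __init__(self, targets, responses, dimension: str = "azimuth"):
        _check_dimension(dimension)
        self.targets = np.asarray(targets, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.targets.shape != self.responses.shape:
            raise ConfigurationError("targets and responses must be paired")
        if len(self.targets) < 2:
            raise ConfigurationError("a fit needs at least 2 trials")
        if np.ptp(self.targets) == 0:
            raise DegenerateSignalError(
                "fit undefined: all targets identical (zero spread)"
            )
        self.dimension = dimension

    @classmethod
    def from_trials(cls, trials, dimension: str = "azimuth") -> "LocalizationModel":
        _check_dimension(dimension)
        t = [tr.target(dimension) for tr in trials]
        r = [tr.response(dimension) for tr in trials]
        return cls(t, r, dimension)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dimension: str = "azimuth"):
        _check_dimension(dimension)
        return cls(
            df[f"target_{dimension}"].to_numpy(),
            df[f"response_{dimension}"].to_numpy(),
            dimension,
        )

    def fit(self) -> "LocalizationResults":
        x, y = self.targets, self.responses
        n = len(x)
        xm, ym = x.mean(), y.mean()
        sxx = np.sum((x - xm) ** 2)
        gain = float(np.sum((x - xm) * (y - ym)) / sxx)
        bias = float(ym - gain * xm)
        resid = y - (bias + gain * x)
        ssr = float(np.sum(resid**2))
        syy = float(np.sum((y - ym) ** 2))
        if syy == 0.0:
            # constant response: no target–response relationship
            rsq = 0.0
        else:
            rsq = float(1.0 - ssr / syy)
            rsq = min(max(rsq, 0.0), 1.0)
        dof = n - 2
        sigma2 = ssr / dof if dof > 0 else np.nan
        se_gain = float(np.sqrt(sigma2 / sxx)) if dof > 0 else np.nan
        se_bias = (
            float(np.sqrt(sigma2 * (1.0 / n + xm**2 / sxx))) if dof > 0 else np.nan
        )
        mae = float(np.mean(np.abs(y - x)))
        return LocalizationResults(
            model=self,
            dimension=self.dimension,
            gain=gain,
            bias=bias,
            rsquared=rsq,
            mae=mae,
            n_trials=n,
            bse={"gain": se_gain, "bias": se_bias},
            df_resid=dof,
        )


@dataclass
class LocalizationResults:
    """Estimates from a :class:`LocalizationModel` fit.

    ``mae`` is the mean absolute target–response error of the same trials
    (a model-free accuracy summary, not a regression residual statistic).
    """

    model: LocalizationModel
    dimension: str
    gain: float
    bias: float
    rsquared: float
    mae: float
    n_trials: int
    bse: dict = field(default_factory=dict)
    df_resid: int = 0

    def conf_int(self, alpha: float = 0.05) -> dict:
        """t-based confidence intervals for gain and bias."""
        if self.df_resid <= 0:
            return {k: (np.nan, np.nan) for k in ("gain", "bias")}
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return {
            "gain": (self.gain - tcrit * self.bse["gain"], self.gain + tcrit * self.bse["gain"]),
            "bias": (self.bias - tcrit * self.bse["bias"], self.bias + tcrit * self.bse["bias"]),
        }

    def predict(self, targets) -> np.ndarray:
        return self.bias + self.gain * np.asarray(targets, dtype=float)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Localization fit ({self.dimension}), n = {self.n_trials}",
            f"  gain g  = {self.gain:8.4f}  (se {self.bse['gain']:.4f}, "
            f"95% CI [{ci['gain'][0]:.4f}, {ci['gain'][1]:.4f}])",
            f"  bias b  = {self.bias:8.4f}° (se {self.bse['bias']:.4f}, "
            f"95% CI [{ci['bias'][0]:.4f}, {ci['bias'][1]:.4f}])",
            f"  r²      = {self.rsquared:8.4f}",
            f"  MAE     = {self.mae:8.4f}°",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Target–response scatter with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.targets, self.model.responses
        ax.scatter(x, y, s=12, alpha=0.6)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.predict(grid), "r-",
                label=f"g={self.gain:.2f}, b={self.bias:.1f}°")
        ax.plot(grid, grid, "k--", lw=0.8, label="perfect")
        ax.set_xlabel(f"target {self.dimension} (°)")
        ax.set_ylabel(f"response {self.dimension} (°)")
        ax.legend()
        return ax


def fit_localization(trials, dimension: str) -> LocalizationResults:
    """Fit the target→response regression over a list of trials."""
    return LocalizationModel.from_trials(trials, dimension).fit()


def pool_conditions(
    trials_df: pd.DataFrame, by, dimensions=DIMENSIONS
) -> pd.DataFrame:
    """Fit per group after pooling trials at the trial level.

    ``by`` is a list of grouping columns (e.g. ``["condition",
    "stimulus"]``).  Returns one row per group × dimension with gain,
    bias, r², MAE and the trial count.
    """
    by = [by] if isinstance(by, str) else list(by)
    missing = [k for k in by if k not in trials_df.columns]
    if missing:
        raise ConfigurationError(f"unknown grouping key(s): {missing}")
    rows = []
    for keys, grp in trials_df.groupby(by, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for dim in dimensions:
            res = LocalizationModel.from_dataframe(grp, dim).fit()
            rows.append(
                dict(zip(by, keys))
                | {
                    "dimension": dim,
                    "gain": res.gain,
                    "bias": res.bias,
                    "r_squared": res.rsquared,
                    "mae": res.mae,
                    "n_trials": res.n_trials,
                }
            )
    return pd.DataFrame(rows)
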