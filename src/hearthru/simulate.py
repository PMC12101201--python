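"""Simulators for listener responses and head-movement trajectories.

Responses follow the same linear target→response model the analysis fits:
response = bias + gain·target + Gaussian scatter, per dimension, with
reaction times generated as the reciprocal of a truncated-normal
promptness draw (which yields the positively skewed RT distributions seen
in human data).  Head movements are minimum-jerk reorientations — the
standard smooth model of goal-directed movements — whose closed-form
speed profile peaks at 15/8 · amplitude / duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import BehavioralModel, TrajectoryParams
from .exceptions import ConfigurationError
from .localization import Trajectory, Trial, VELOCITY_THRESHOLD

#: Peak-speed factor of a minimum-jerk profile: v_peak = 15/8 * amp / T.
MIN_JERK_PEAK_FACTOR = 15.0 / 8.0


def simulate_trials(
    model: BehavioralModel,
    targets,
    condition: str = "NH",
    stimulus: str = "BB",
    level: float = 60.0,
    snr: float | None = None,
    listener_id: str = "L01",
    seed: int = 0,
) -> list[Trial]:
    """Draw one simulated localization response per target.

    ``targets`` is a sequence of (azimuth, elevation) pairs within ±90°/
    ±30°.  Deterministic given ``seed``.
    """
    targets = list(targets)
    if not targets:
        raise ConfigurationError("empty target list")
    rng = np.random.default_rng(seed)
    p_az = model.params_for(condition, stimulus, "azimuth")
    p_el = model.params_for(condition, stimulus, "elevation")
    trials = []
    for az_t, el_t in targets:
        if abs(az_t) > 90 or abs(el_t) > 30:
            raise ConfigurationError(
                f"target ({az_t}, {el_t}) outside ±90°/±30°"
            )
        az_r = p_az.bias + p_az.gain * az_t + rng.normal(0.0, p_az.response_sd)
        el_r = p_el.bias + p_el.gain * el_t + rng.normal(0.0, p_el.response_sd)
        # promptness ~ Normal truncated strictly positive; RT = 1/p
        while True:
            prompt = p_az.promptness_mean + rng.normal(0.0, p_az.promptness_sd)
            if prompt > 0:
                break
        trials.append(
            Trial(
                listener_id=listener_id,
                condition=condition,
                stimulus=stimulus,
                level=level,
                snr=snr,
                target_azimuth=float(az_t),
                target_elevation=float(el_t),
                response_azimuth=float(az_r),
                response_elevation=float(el_r),
                reaction_time=1000.0 / prompt,
            )
        )
    return trials


def minimum_jerk_position(s: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on s ∈ [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


@dataclass
class SimulatedTrajectory:
    """A synthetic trajectory with its noiseless ground truth attached.

    ``onset_truth`` is the first time the *noiseless* combined angular
    speed exceeds ``threshold`` (None when the movement never does, e.g. a
    zero-length movement); ``peak_speed`` the closed-form peak of the
    minimum-jerk profile.
    """

    trajectory: Trajectory
    onset_truth: float | None
    offset_truth: float | None
    peak_speed: float
    params: TrajectoryParams


def simulate_trajectory(
    params: TrajectoryParams,
    seed: int = 0,
    threshold: float = VELOCITY_THRESHOLD,
) -> SimulatedTrajectory:
    """Generate a minimum-jerk head reorientation with tracker noise.

    Both dimensions share one time profile, so the combined angular speed
    is hypot(Δaz, Δel) times the minimum-jerk speed shape.  Ground-truth
    onset/offset are the threshold crossings of the noiseless speed,
    solved from the closed form.  Deterministic given ``seed``.
    """
    fs = params.tracker_rate
    t = np.arange(0.0, params.trial_duration / 1000.0, 1.0 / fs)
    t0 = params.movement_latency / 1000.0
    T = params.movement_duration / 1000.0
    d_az = params.end_azimuth - params.start_azimuth
    d_el = params.end_elevation - params.start_elevation
    amp = float(np.hypot(d_az, d_el))
    s = (t - t0) / T
    pos = minimum_jerk_position(s)
    az = params.start_azimuth + d_az * pos
    el = params.start_elevation + d_el * pos

    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        az = az + rng.normal(0.0, params.noise_sd, size=len(t))
        el = el + rng.normal(0.0, params.noise_sd, size=len(t))

    peak_speed = MIN_JERK_PEAK_FACTOR * amp / T
    onset = offset = None
    if peak_speed > threshold:
        # speed(s) = peak * 16 s^2 (1-s)^2; solve the rising crossing
        def f(si):
            return peak_speed * 16 * si**2 * (1 - si) ** 2 - threshold

        s_on = optimize.brentq(f, 1e-9, 0.5)
        onset = t0 + s_on * T
        offset = t0 + (1.0 - s_on) * T
    return SimulatedTrajectory(
        trajectory=Trajectory(time=t, azimuth=az, elevation=el, tracker_rate=fs),
        onset_truth=onset,
        offset_truth=offset,
        peak_speed=peak_speed,
        params=params,
    )
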