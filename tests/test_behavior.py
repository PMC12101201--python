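"""Behavioral simulation, movement detection, and localization fits."""

import numpy as np
import pandas as pd
import pytest

from hearthru import (
    BehavioralModel,
    ConfigurationError,
    DegenerateSignalError,
    LocalizationModel,
    ResponseParams,
    TrajectoryParams,
    detect_movement,
    fit_localization,
    mean_absolute_error,
    pool_conditions,
    promptness,
    simulate_trajectory,
    simulate_trials,
)
from hearthru.io import trials_to_frame
from hearthru.simulate import MIN_JERK_PEAK_FACTOR

TARGETS = [(a, e) for a in range(-90, 91, 30) for e in (-30, 0, 30)]


def _model(**kw):
    return BehavioralModel({("*", "*", "azimuth"): ResponseParams(**kw),
                            ("*", "*", "elevation"): ResponseParams(**kw)})


# -- trial simulation ------------------------------------------------------


def test_noiseless_identity_model_reproduces_targets():
    m = _model(gain=1.0, bias=0.0, response_sd=0.0)
    for t in simulate_trials(m, TARGETS, seed=0):
        assert t.response_azimuth == t.target_azimuth
        assert t.response_elevation == t.target_elevation


def test_constant_promptness_gives_250ms_reaction_times():
    m = _model(promptness_mean=4.0, promptness_sd=0.0)
    rts = [t.reaction_time for t in simulate_trials(m, TARGETS, seed=1)]
    assert all(rt == pytest.approx(250.0) for rt in rts)


def test_trial_simulation_deterministic_and_validates():
    m = _model(response_sd=5.0)
    a = simulate_trials(m, TARGETS, seed=42)
    b = simulate_trials(m, TARGETS, seed=42)
    assert [t.response_azimuth for t in a] == [t.response_azimuth for t in b]
    with pytest.raises(ConfigurationError):
        simulate_trials(m, [], seed=0)
    with pytest.raises(ConfigurationError):
        simulate_trials(m, [(120.0, 0.0)], seed=0)


def test_parameter_recovery_within_confidence_intervals():
    """Simulate with known (gain, bias); the fit's 95% CI covers them in
    ≥90% of replicates at n = 500."""
    m = _model(gain=0.97, bias=0.72, response_sd=6.81 * np.sqrt(np.pi / 2))
    rng = np.random.default_rng(7)
    hits_gain = hits_bias = 0
    n_rep = 100
    for i in range(n_rep):
        targets = np.stack(
            [rng.uniform(-90, 90, 500), rng.uniform(-30, 30, 500)], axis=1
        )
        trials = simulate_trials(m, targets, seed=int(rng.integers(2**31)))
        res = fit_localization(trials, "azimuth")
        ci = res.conf_int()
        hits_gain += ci["gain"][0] <= 0.97 <= ci["gain"][1]
        hits_bias += ci["bias"][0] <= 0.72 <= ci["bias"][1]
    assert hits_gain >= 90
    assert hits_bias >= 90


def test_mae_converges_to_folded_normal_mean():
    """With gain 1, bias 0 and scatter σ, MAE → σ·sqrt(2/π) (checked 5%)."""
    sigma = 10.0
    m = _model(gain=1.0, bias=0.0, response_sd=sigma)
    rng = np.random.default_rng(11)
    targets = np.stack(
        [rng.uniform(-90, 90, 2000), rng.uniform(-30, 30, 2000)], axis=1
    )
    trials = simulate_trials(m, targets, seed=3)
    mae = mean_absolute_error(trials, "azimuth")
    assert mae == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.05)


# -- trajectories and movement detection ----------------------------------


def test_minimum_jerk_peak_speed_closed_form():
    """40° in 400 ms peaks at 15/8 · 40/0.4 = 187.5 °/s."""
    p = TrajectoryParams(end_azimuth=40.0, movement_duration=400.0, noise_sd=0.0)
    sim = simulate_trajectory(p, seed=0)
    assert sim.peak_speed == pytest.approx(MIN_JERK_PEAK_FACTOR * 40.0 / 0.4)
    assert sim.peak_speed == pytest.approx(187.5)


def test_stationary_head_flagged_no_movement():
    p = TrajectoryParams(end_azimuth=0.0, end_elevation=0.0, noise_sd=0.0)
    sim = simulate_trajectory(p, seed=0)
    assert sim.onset_truth is None
    assert detect_movement(sim.trajectory) is None


def test_trajectory_determinism():
    p = TrajectoryParams(noise_sd=1.0)
    a = simulate_trajectory(p, seed=5)
    b = simulate_trajectory(p, seed=5)
    np.testing.assert_array_equal(a.trajectory.azimuth, b.trajectory.azimuth)


def test_detected_onset_within_one_tracker_sample_of_truth():
    p = TrajectoryParams(
        end_azimuth=40.0, movement_latency=300.0, movement_duration=400.0,
        tracker_rate=120.0, noise_sd=0.0,
    )
    sim = simulate_trajectory(p, seed=0)
    ev = detect_movement(sim.trajectory)
    assert ev is not None
    assert abs(ev.onset - sim.onset_truth) <= 1.0 / 120.0
    assert ev.reaction_time == pytest.approx(ev.onset * 1000.0)
    # offset lands after the movement and the final position at the target
    assert ev.offset > sim.offset_truth - 1.0 / 120.0
    assert ev.final_azimuth == pytest.approx(40.0, abs=0.5)


def test_detection_invariant_to_constant_offset():
    p = TrajectoryParams(end_azimuth=30.0, noise_sd=0.2)
    sim = simulate_trajectory(p, seed=9)
    ev1 = detect_movement(sim.trajectory)
    t2 = sim.trajectory
    t2.azimuth = t2.azimuth + 55.0
    t2.elevation = t2.elevation - 12.0
    ev2 = detect_movement(t2)
    assert ev1.onset == ev2.onset and ev1.offset == ev2.offset


def test_detection_flips_at_velocity_criterion():
    """Bisection over peak speeds localises the flip near 20 °/s."""

    def is_detected(peak):
        T = 1000.0
        amp = peak * (T / 1000.0) / MIN_JERK_PEAK_FACTOR
        p = TrajectoryParams(
            end_azimuth=amp, movement_duration=T, trial_duration=2000.0,
            movement_latency=300.0, noise_sd=0.0,
        )
        sim = simulate_trajectory(p, seed=0)
        return detect_movement(sim.trajectory, threshold=20.0) is not None

    lo, hi = 10.0, 40.0
    assert not is_detected(lo) and is_detected(hi)
    for _ in range(30):
        mid = (lo + hi) / 2
        if is_detected(mid):
            hi = mid
        else:
            lo = mid
    assert (lo + hi) / 2 == pytest.approx(20.0, abs=0.5)


# -- localization fits -----------------------------------------------------


def test_perfect_responses_give_unit_gain_zero_bias_unit_r2():
    """A perfect localizer: gain 1, bias 0°, r² 1.0, MAE 0°."""
    targets = np.arange(-90.0, 91.0, 10.0)
    res = LocalizationModel(targets, targets.copy(), "azimuth").fit()
    assert res.gain == 1.0
    assert res.bias == 0.0
    assert res.rsquared == 1.0
    assert res.mae == 0.0


def test_constant_response_gives_zero_gain():
    targets = np.array([-30.0, 0.0, 30.0, 60.0])
    res = LocalizationModel(targets, np.full(4, 12.5), "azimuth").fit()
    assert res.gain == pytest.approx(0.0, abs=1e-12)
    assert res.bias == pytest.approx(12.5)
    assert res.rsquared == 0.0


def test_three_point_hand_computed_least_squares():
    """targets (−30,0,30), responses (−20,5,30): g = 25/30, b = 5."""
    res = LocalizationModel([-30.0, 0.0, 30.0], [-20.0, 5.0, 30.0]).fit()
    assert res.gain == pytest.approx(25.0 / 30.0)
    assert res.bias == pytest.approx(5.0)


def test_fit_matches_scipy_linregress():
    rng = np.random.default_rng(2)
    x = rng.uniform(-90, 90, 200)
    y = 0.8 * x + 3.0 + rng.normal(0, 5, 200)
    res = LocalizationModel(x, y).fit()
    from scipy.stats import linregress

    ref = linregress(x, y)
    assert res.gain == pytest.approx(ref.slope, rel=1e-12)
    assert res.bias == pytest.approx(ref.intercept, rel=1e-12)
    assert res.rsquared == pytest.approx(ref.rvalue**2, rel=1e-9)
    assert res.bse["gain"] == pytest.approx(ref.stderr, rel=1e-9)


def test_degenerate_fits_rejected():
    with pytest.raises(ConfigurationError):
        LocalizationModel([1.0], [1.0])
    with pytest.raises(DegenerateSignalError):
        LocalizationModel([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


def test_mae_basics_and_negation_invariance():
    from hearthru import Trial

    trials = [
        Trial(target_azimuth=10.0, response_azimuth=15.0),
        Trial(target_azimuth=-20.0, response_azimuth=-35.0),
    ]
    assert mean_absolute_error(trials, "azimuth") == pytest.approx(10.0)
    flipped = [
        Trial(target_azimuth=-t.target_azimuth, response_azimuth=-t.response_azimuth)
        for t in trials
    ]
    assert mean_absolute_error(flipped, "azimuth") == mean_absolute_error(
        trials, "azimuth"
    )
    with pytest.raises(ConfigurationError):
        mean_absolute_error([], "azimuth")


def test_promptness_reciprocal_and_monotone():
    assert promptness(250.0) == 4.0
    assert promptness(1000.0) == 1.0
    rts = np.linspace(100, 2000, 50)
    vals = [promptness(rt) for rt in rts]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ConfigurationError):
        promptness(0.0)


# -- pooling ---------------------------------------------------------------


def _trial_frame(seed=0, condition="NH", n=60):
    m = _model(gain=0.9, bias=1.0, response_sd=6.0)
    rng = np.random.default_rng(seed)
    targets = np.stack([rng.uniform(-90, 90, n), rng.uniform(-30, 30, n)], axis=1)
    trials = simulate_trials(m, targets, condition=condition, seed=seed)
    return trials_to_frame(trials)


def test_pooling_single_group_equals_ungrouped_fit():
    df = _trial_frame()
    pooled = pool_conditions(df, ["condition"])
    direct = LocalizationModel.from_dataframe(df, "azimuth").fit()
    row = pooled[pooled["dimension"] == "azimuth"].iloc[0]
    assert row["gain"] == pytest.approx(direct.gain)
    assert row["mae"] == pytest.approx(direct.mae)


def test_pooling_duplicated_trials_leaves_fit_unchanged():
    df = _trial_frame()
    doubled = pd.concat([df, df], ignore_index=True)
    a = pool_conditions(df, ["condition"])
    b = pool_conditions(doubled, ["condition"])
    for dim in ("azimuth", "elevation"):
        ra = a[a["dimension"] == dim].iloc[0]
        rb = b[b["dimension"] == dim].iloc[0]
        assert ra["gain"] == pytest.approx(rb["gain"])
        assert ra["bias"] == pytest.approx(rb["bias"])


def test_pooled_mae_is_count_weighted_mean_of_block_maes():
    df1, df2 = _trial_frame(1, n=40), _trial_frame(2, n=80)
    both = pd.concat([df1, df2], ignore_index=True)
    mae1 = pool_conditions(df1, "condition").query("dimension=='azimuth'")["mae"].iloc[0]
    mae2 = pool_conditions(df2, "condition").query("dimension=='azimuth'")["mae"].iloc[0]
    pooled = pool_conditions(both, "condition").query("dimension=='azimuth'")["mae"].iloc[0]
    assert pooled == pytest.approx((40 * mae1 + 80 * mae2) / 120)


def test_unknown_grouping_key_rejected():
    with pytest.raises(ConfigurationError, match="grouping"):
        pool_conditions(_trial_frame(), ["nonexistent"])
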