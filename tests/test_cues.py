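"""ITD/ILD extraction and spectral maps: oracles, symmetry, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearthru import (
    ConfigurationError,
    DegenerateSignalError,
    extract_ild,
    extract_itd,
    spectral_difference,
    spectral_map,
)

FS = 44100
SAMPLE_US = 1e6 / FS


def _click_pair(delay_samples, n=2048, seed=0):
    """Identical broadband bursts with a pure interaural sample delay."""
    rng = np.random.default_rng(seed)
    burst = rng.standard_normal(256)
    left = np.zeros(n)
    right = np.zeros(n)
    start = 600
    left[start : start + 256] = burst
    right[start - delay_samples : start - delay_samples + 256] = burst
    return left, right


def test_itd_zero_for_identical_ears():
    l, _ = _click_pair(0)
    assert extract_itd(l, l.copy(), FS) == 0.0


@pytest.mark.parametrize("delay", [-31, -10, 5, 31])
def test_itd_matches_imposed_sample_delay(delay):
    """Right advanced by d samples → +d/fs; right delayed → negative."""
    l, r = _click_pair(delay)
    assert extract_itd(l, r, FS) == pytest.approx(delay / FS * 1e6, abs=1e-9)


def test_itd_sample_delay_oracle_up_to_900us():
    for delay in range(0, 41, 8):  # up to 40 samples ≈ 907 µs
        l, r = _click_pair(delay)
        assert abs(extract_itd(l, r, FS) - delay * SAMPLE_US) <= SAMPLE_US


def test_ild_known_amplitude_ratios():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(2048)
    assert extract_ild(x, x, FS) == pytest.approx(0.0, abs=1e-12)
    assert extract_ild(x, 2 * x, FS) == pytest.approx(20 * np.log10(2), abs=1e-9)
    assert extract_ild(2 * x, x, FS) == pytest.approx(-20 * np.log10(2), abs=1e-9)


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_channel_swap_antisymmetry(seed):
    """extract_itd(L,R) = −extract_itd(R,L); same for ILD, exactly."""
    rng = np.random.default_rng(seed)
    l = rng.standard_normal(1500)
    r = rng.standard_normal(1500)
    assert extract_itd(l, r, FS) == -extract_itd(r, l, FS)
    assert extract_ild(l, r, FS) == pytest.approx(-extract_ild(r, l, FS), abs=1e-12)


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_itd_bounded_by_max_lag_on_uncorrelated_noise(seed):
    rng = np.random.default_rng(seed)
    l = rng.standard_normal(2048)
    r = rng.standard_normal(2048)
    assert abs(extract_itd(l, r, FS, max_lag=1e-3)) <= 1000.0


def test_cue_amplitude_invariance():
    rng = np.random.default_rng(9)
    l, r = _click_pair(7, seed=9)
    r = r + 0.1 * rng.standard_normal(len(r))
    for scale in (0.25, 4.0):
        assert extract_itd(scale * l, scale * r, FS) == extract_itd(l, r, FS)
        assert extract_ild(scale * l, scale * r, FS) == pytest.approx(
            extract_ild(l, r, FS), abs=1e-9
        )


def test_subsample_interpolation_refines_fractional_delay():
    """With parabolic refinement a fractional delay lands between samples."""
    n = 2048
    f = np.fft.rfftfreq(n, 1 / FS)
    rng = np.random.default_rng(4)
    spec = np.fft.rfft(rng.standard_normal(n))
    lo = (f > 100) & (f < 1400)
    spec[~lo] = 0
    base = np.fft.irfft(spec, n)
    frac = 10.4 / FS
    shifted = np.fft.irfft(spec * np.exp(+2j * np.pi * f * frac), n)
    coarse = extract_itd(base, shifted, FS)
    fine = extract_itd(base, shifted, FS, subsample=True)
    assert coarse == pytest.approx(10 * SAMPLE_US, abs=1e-9)
    assert abs(fine - 10.4 * SAMPLE_US) < abs(coarse - 10.4 * SAMPLE_US)


def test_degenerate_inputs_raise():
    z = np.zeros(2048)
    with pytest.raises(DegenerateSignalError):
        extract_ild(z, z, FS)
    with pytest.raises(ConfigurationError):
        extract_itd(np.zeros(100), np.zeros(100), FS)  # shorter than filter
    with pytest.raises(ConfigurationError):
        extract_itd(np.zeros(2048), np.zeros(1024), FS)


def test_spectral_notch_tracks_elevation(nh_hrirs_full):
    m = spectral_map(nh_hrirs_full, "left")
    notches = m.notch_frequencies()
    assert np.all(np.diff(notches) > 0)  # centre rises with elevation
    # matches the parametric model: base 8 kHz + 50 Hz/°
    expect = 8000.0 + 50.0 * m.elevations
    np.testing.assert_allclose(notches, expect, rtol=0.05)


def test_transparency_flattens_spectra_above_5khz(nh_hrirs_full):
    from hearthru import TransparencyParams, apply_transparency

    dev = apply_transparency(nh_hrirs_full, TransparencyParams(), seed=2)
    m = spectral_map(dev, "left")
    hi = m.frequencies > 5000.0
    spread = np.ptp(m.magnitude_db[:, hi], axis=0)
    assert spread.max() < 1.0  # elevation-independent above the cutoff

    m_nh = spectral_map(nh_hrirs_full, "left")
    d = spectral_difference(m_nh, m)
    worst = np.abs(d.magnitude_db).max(axis=0)
    assert m.frequencies[np.argmax(worst)] > 5000.0


def test_spectral_difference_identities(nh_hrirs_full):
    a = spectral_map(nh_hrirs_full, "left")
    zero = spectral_difference(a, a)
    np.testing.assert_array_equal(zero.magnitude_db, 0.0)


def test_spectral_map_rejects_zero_ir(nh_hrirs):
    from hearthru import HRIRSet

    s = HRIRSet(sample_rate=FS)
    s.put(0.0, 0.0, np.zeros(512), np.zeros(512))
    with pytest.raises(DegenerateSignalError):
        spectral_map(s, "left")
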