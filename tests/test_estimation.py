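"""Estimation statistics: BCa intervals and permutation tests."""

import math
from itertools import combinations, product

import numpy as np
import pytest

from hearthru import (
    ConfigurationError,
    estimate_difference,
    mean_diff_bca,
    permutation_pvalue,
)


def test_identical_samples_zero_difference():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = mean_diff_bca(x, x.copy(), n_boot=500, seed=0)
    assert res.mean_difference == 0.0
    assert res.ci_low <= 0.0 <= res.ci_high


def test_translation_invariance():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
    a = mean_diff_bca(x, y, n_boot=999, seed=3)
    b = mean_diff_bca(x + 100.0, y + 100.0, n_boot=999, seed=3)
    assert a.mean_difference == pytest.approx(b.mean_difference)
    assert a.ci_low == pytest.approx(b.ci_low, abs=1e-9)
    assert a.ci_high == pytest.approx(b.ci_high, abs=1e-9)


def test_swap_negates_difference_and_mirrors_interval():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 25), rng.normal(0.8, 1.2, 25)
    a = mean_diff_bca(x, y, n_boot=1999, seed=5)
    b = mean_diff_bca(y, x, n_boot=1999, seed=5)
    assert a.mean_difference == pytest.approx(-b.mean_difference)
    # CIs mirror within bootstrap resolution
    assert a.ci_low == pytest.approx(-b.ci_high, abs=0.15)
    assert a.ci_high == pytest.approx(-b.ci_low, abs=0.15)
    pa = permutation_pvalue(x, y, n_perm=999, seed=5)
    pb = permutation_pvalue(y, x, n_perm=999, seed=5)
    assert pa == pytest.approx(pb, abs=0.02)


def test_widening_alpha_widens_interval():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
    narrow = mean_diff_bca(x, y, n_boot=1999, alpha=0.1, seed=7)
    wide = mean_diff_bca(x, y, n_boot=1999, alpha=0.01, seed=7)
    assert wide.ci_low < narrow.ci_low
    assert wide.ci_high > narrow.ci_high


def test_degenerate_samples_collapse_flagged():
    x = np.full(5, 3.0)
    y = np.full(5, 4.5)
    res = mean_diff_bca(x, y, seed=0)
    assert res.mean_difference == pytest.approx(1.5)
    assert res.ci_low == res.ci_high == res.mean_difference
    assert any("degenerate" in f for f in res.flags)


def test_bca_coverage_of_known_mean_difference():
    """95% BCa interval covers the true difference 1 in 93–97% of
    replicates (Normal(0,1) vs Normal(1,1), n = 50 each).

    The replicate count is large enough that the Monte-Carlo error of the
    measured coverage (±0.4%) is small against the width of the band;
    data and bootstrap streams are seeded independently per replicate.
    """
    n_rep, covered = 3000, 0
    for i in range(n_rep):
        rng = np.random.default_rng(1_000_000 + i)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        res = mean_diff_bca(x, y, n_boot=1999, seed=i)
        if res.ci_low <= 1.0 <= res.ci_high:
            covered += 1
    assert 0.93 <= covered / n_rep <= 0.97


def test_identical_samples_permutation_p_near_one():
    x = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
    assert permutation_pvalue(x, x.copy(), n_perm=999, seed=0) >= 0.99


def test_zero_variance_permutation_p_is_one():
    x = np.full(6, 2.0)
    assert permutation_pvalue(x, x.copy(), n_perm=99, seed=0) == 1.0


def test_permutation_type_i_error_calibrated():
    """Under the null, P(p < 0.05) = 0.05 ± 0.02 over 1000 simulations."""
    rng = np.random.default_rng(0)
    n_sim, hits = 1000, 0
    for i in range(n_sim):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        p = permutation_pvalue(x, y, n_perm=4999, seed=int(rng.integers(2**31)))
        if p < 0.05:
            hits += 1
    assert abs(hits / n_sim - 0.05) <= 0.02


def _welch(x, y):
    nx, ny = len(x), len(y)
    return (y.mean() - x.mean()) / math.sqrt(
        x.var(ddof=1) / nx + y.var(ddof=1) / ny
    )


def test_exact_enumeration_matches_brute_force():
    """For n ≤ 8 the enumerated p equals a from-scratch full count."""
    x = np.array([1.1, 2.3, 0.7, 1.9])
    y = np.array([3.0, 4.2, 2.8, 3.9])
    p_impl = permutation_pvalue(x, y, exact=True, seed=0)
    pooled = np.concatenate([x, y])
    t_obs = abs(_welch(x, y))
    count, total = 0, 0
    for ix in combinations(range(8), 4):
        mask = np.zeros(8, dtype=bool)
        mask[list(ix)] = True
        if abs(_welch(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
            count += 1
        total += 1
    assert p_impl == pytest.approx(count / total)


def test_paired_exact_enumeration_matches_sign_flip_brute_force():
    d = np.array([0.8, 1.1, 0.5, 1.4, 0.9])
    x = np.zeros(5)
    p_impl = permutation_pvalue(x, d, paired=True, exact=True, seed=0)

    def tstat(v):
        return v.mean() / (v.std(ddof=1) / math.sqrt(len(v)))

    t_obs = abs(tstat(d))
    count = 0
    for signs in product([-1, 1], repeat=5):
        if abs(tstat(np.array(signs) * d)) >= t_obs - 1e-12:
            count += 1
    assert p_impl == pytest.approx(count / 32)


def test_cross_check_against_scipy_permutation_test():
    """Monte-Carlo p agrees with scipy's independent implementation."""
    from scipy import stats

    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.9, 1, 15)
    p_ours = permutation_pvalue(x, y, n_perm=4999, seed=1)

    def stat(a, b, axis):
        return stats.ttest_ind(a, b, axis=axis, equal_var=False).statistic

    ref = stats.permutation_test(
        (x, y), stat, permutation_type="independent",
        n_resamples=4999, rng=np.random.default_rng(2),
    )
    assert p_ours == pytest.approx(ref.pvalue, abs=0.02)


def test_affine_invariance_of_p():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 1, 10)
    y = rng.normal(1, 1, 10)
    p1 = permutation_pvalue(x, y, n_perm=999, seed=4)
    p2 = permutation_pvalue(3.0 * x - 7.0, 3.0 * y - 7.0, n_perm=999, seed=4)
    assert p1 == p2


def test_full_contrast_combines_interval_and_p():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 10)
    y = x + rng.normal(1.0, 0.3, 10)
    res = estimate_difference(x, y, n_boot=999, n_perm=999, paired=True, seed=6)
    assert res.ci_low <= res.mean_difference <= res.ci_high
    assert 0 < res.p_value <= 1
    assert res.p_value < 0.05  # clear paired effect
    assert "paired" in res.summary()


def test_too_small_samples_rejected():
    with pytest.raises(ConfigurationError):
        mean_diff_bca([1.0], [2.0, 3.0])
    with pytest.raises(ConfigurationError):
        permutation_pvalue([1.0], [2.0])
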