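"""Estimation statistics for condition contrasts.

Differences between conditions are reported as effect sizes with
uncertainty rather than bare significance: the mean difference with a 95%
bias-corrected-and-accelerated (BCa) bootstrap confidence interval, plus a
permutation p-value (Welch t statistic, 5000 reshuffles, add-one
smoothed so it can never be exactly zero).

Because the same listeners are measured in both conditions, the default
contrast mode is paired: the bootstrap resamples within-listener
differences and the permutation test flips their signs.  Unpaired
variants are available for independent groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError

DEFAULT_N_BOOT = 5000
DEFAULT_N_PERM = 5000


@dataclass
class EstimationResult:
    """Mean difference (y − x) with BCa interval and permutation p."""

    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    n_boot: int = 0
    n_perm: int = 0
    alpha: float = 0.05
    paired: bool = False
    seed: int = 0
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        mode = "paired" if self.paired else "unpaired"
        s = (
            f"mean difference = {self.mean_difference:.4g} "
            f"[{100 * (1 - self.alpha):.0f}% BCa {self.ci_low:.4g}, "
            f"{self.ci_high:.4g}] ({mode}), p = {p}"
        )
        if self.flags:
            s += f"  [flags: {', '.join(self.flags)}]"
        return s


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    denom = math.sqrt(vx + vy)
    if denom == 0:
        return 0.0
    return (y.mean() - x.mean()) / denom


def mean_diff_bca(
    x,
    y,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    paired: bool = False,
    seed: int = 0,
) -> EstimationResult:
    """Mean difference mean(y) − mean(x) with a BCa bootstrap interval.

    The BCa interval corrects the percentile interval with a bias term z0
    (from the fraction of bootstrap replicates below the point estimate)
    and an acceleration term a (from jackknife skewness); it is computed
    with :func:`scipy.stats.bootstrap`.  Paired mode bootstraps the
    within-pair differences.  Deterministic given ``seed``.

    Degenerate inputs (zero variance everywhere) collapse the interval to
    the point estimate and are flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each sample needs at least 2 observations")
    if paired and len(x) != len(y):
        raise ConfigurationError("paired samples must have equal length")
    est = float(y.mean() - x.mean())
    flags: list[str] = []

    degenerate = (
        (np.ptp(y - x) == 0) if paired else (np.ptp(x) == 0 and np.ptp(y) == 0)
    )
    if degenerate:
        flags.append("degenerate: zero variance, interval collapsed to the point")
        return EstimationResult(est, est, est, None, n_boot, 0, alpha, paired, seed, flags)

    rng = np.random.default_rng(seed)
    if paired:
        data = (y - x,)
        statistic = np.mean
    else:
        data = (x, y)

        def statistic(xs, ys, axis=-1):  # type: ignore[misc]
            return np.mean(ys, axis=axis) - np.mean(xs, axis=axis)

    res = stats.bootstrap(
        data,
        statistic,
        n_resamples=n_boot,
        confidence_level=1 - alpha,
        method="BCa",
        paired=False,
        vectorized=True,
        axis=-1,
        rng=rng,
    )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not (lo <= est <= hi):
        flags.append("pathological: point estimate outside the BCa interval")
    return EstimationResult(est, lo, hi, None, n_boot, 0, alpha, paired, seed, flags)


def permutation_pvalue(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    paired: bool = False,
    seed: int = 0,
    exact: bool | None = None,
) -> float:
    """Two-sided permutation p-value for the difference in means.

    Unpaired: labels are reshuffled between the samples and the Welch
    (unequal-variance) t statistic recomputed; paired: the signs of the
    within-pair differences are flipped and a one-sample t recomputed.
    Monte-Carlo p-values use add-one smoothing,
    p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm), and are deterministic given
    ``seed``.  When ``exact`` is true (or the number of distinct
    rearrangements is below ``n_perm`` and ``exact`` is unset), all
    rearrangements are enumerated and p = #{|t*| ≥ |t|} / total.

    Zero combined variance returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) < 3:
        raise ConfigurationError("combined sample size must be at least 3")
    if paired:
        if len(x) != len(y):
            raise ConfigurationError("paired samples must have equal length")
        return _paired_permutation(y - x, n_perm, seed, exact)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0

    t_obs = abs(_welch_t(x, y))
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    n_exact = math.comb(n, nx)
    if exact or (exact is None and n_exact <= n_perm):
        count = 0
        for ix in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(ix)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
                count += 1
        return count / n_exact

    rng = np.random.default_rng(seed)
    # vectorized reshuffles: each row of `order` is one random relabelling
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]
    t_all = np.abs(_welch_t_rows(perm[:, :nx], perm[:, nx:]))
    count = int(np.sum(t_all >= t_obs - 1e-12))
    return (1 + count) / (1 + n_perm)


def _welch_t_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic along the last axis for stacked permutations."""
    vx = x.var(ddof=1, axis=-1) / x.shape[-1]
    vy = y.var(ddof=1, axis=-1) / y.shape[-1]
    denom = np.sqrt(vx + vy)
    return np.where(denom == 0, 0.0, (y.mean(axis=-1) - x.mean(axis=-1)) / np.where(denom == 0, 1.0, denom))


def _paired_permutation(d: np.ndarray, n_perm: int, seed: int, exact: bool | None) -> float:
    if np.ptp(d) == 0 and d[0] == 0:
        return 1.0

    def tstat(di):
        sd = di.std(ddof=1, axis=-1)
        m = di.mean(axis=-1)
        return np.where(sd == 0, 0.0, m / np.where(sd == 0, 1.0, sd / math.sqrt(di.shape[-1])))

    t_obs = abs(float(tstat(d)))
    n = len(d)
    if exact or (exact is None and 2**n <= n_perm):
        signs = np.array(
            [[1 if (i >> b) & 1 else -1 for b in range(n)] for i in range(2**n)]
        )
        t_all = np.abs(tstat(signs * d))
        return float(np.sum(t_all >= t_obs - 1e-12)) / (2**n)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_all = np.abs(tstat(signs * d))
    count = int(np.sum(t_all >= t_obs - 1e-12))
    return (1 + count) / (1 + n_perm)


def estimate_difference(
    x,
    y,
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    paired: bool = True,
    seed: int = 0,
) -> EstimationResult:
    """Full contrast: BCa interval plus permutation p in one result.

    Paired by default, matching a within-listener condition contrast.
    """
    res = mean_diff_bca(x, y, n_boot=n_boot, alpha=alpha, paired=paired, seed=seed)
    res.p_value = permutation_pvalue(x, y, n_perm=n_perm, paired=paired, seed=seed + 1)
    res.n_perm = n_perm
    return res
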