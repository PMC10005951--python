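"""Closed-form statistical utilities: correlation power, two-sample
t-test sample size, and a variance-ratio (F) comparison.

Correlation power uses the Fisher z approximation: under H1 the
transformed sample correlation atanh(r_hat) is approximately normal with
mean atanh(r) and standard deviation 1/sqrt(n - 3), so the power of the
level-alpha test of zero correlation is
Phi(|z_nc| - z_crit) + Phi(-|z_nc| - z_crit) with
z_nc = atanh(r) * sqrt(n - 3).

Sample size for the two-sample t-test is the smallest integer per-group
n whose exact noncentral-t power meets the requested power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, InvalidArgumentError

__all__ = [
    "PowerSpec",
    "correlation_power",
    "two_sample_t_sample_size",
    "variance_ratio_test",
    "VarianceRatioResult",
]


@dataclass(frozen=True)
class PowerSpec:
    """Effect size, sample size, alpha and tail count for a power query."""

    effect: float
    n: int
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if self.tails not in (1, 2):
            raise InvalidArgumentError("tails must be 1 or 2")


def correlation_power(r: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the test of zero Pearson correlation (Fisher z method)."""
    spec = PowerSpec(r, n, alpha, tails)
    if abs(r) >= 1.0:
        raise InvalidArgumentError("|r| must be < 1")
    if n < 4:
        raise InvalidArgumentError("n must be >= 4 for correlation power")
    z_crit = stats.norm.ppf(1.0 - spec.alpha / spec.tails)
    z_nc = np.arctanh(r) * np.sqrt(n - 3)
    power = stats.norm.cdf(abs(z_nc) - z_crit) + stats.norm.cdf(-abs(z_nc) - z_crit)
    return float(power)


def _t_power(n: int, d: float, alpha: float, tails: int) -> float:
    """Exact noncentral-t power of the two-sample t-test at per-group n."""
    df = 2 * n - 2
    nc = abs(d) * np.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    power = stats.nct.sf(t_crit, df, nc)
    if tails == 2:
        power += stats.nct.cdf(-t_crit, df, nc)
    return float(power)


def two_sample_t_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.8, tails: int = 2,
    max_n: int = 10_000_000,
) -> int:
    """Smallest per-group n with two-sample t-test power >= ``power``.

    Bisection on the exact noncentral-t power, which is monotone in n.
    """
    if d == 0:
        raise InvalidArgumentError("effect size d must be nonzero")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise InvalidArgumentError("tails must be 1 or 2")
    if not alpha < power < 1.0:
        raise InvalidArgumentError("power must be in (alpha, 1)")

    lo = 2
    if _t_power(lo, d, alpha, tails) >= power:
        return lo
    hi = 4
    while _t_power(hi, d, alpha, tails) < power:
        hi *= 2
        if hi > max_n:
            raise ConvergenceError(f"requested power unattainable below n = {max_n}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _t_power(mid, d, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid
    return hi


class VarianceRatioResult(NamedTuple):
    f_stat: float
    p_value: float
    df: tuple


def variance_ratio_test(var_a: float, n_a: int, var_b: float, n_b: int) -> VarianceRatioResult:
    """Two-sided F test comparing two sample variances.

    F = var_a / var_b with (n_a - 1, n_b - 1) degrees of freedom;
    p = 2 * min(P(F' >= F), P(F' <= F)), capped at 1.
    """
    if var_a <= 0 or var_b <= 0:
        raise InvalidArgumentError("variances must be positive")
    if n_a < 2 or n_b < 2:
        raise InvalidArgumentError("each group needs at least 2 observations")
    f = var_a / var_b
    dfn, dfd = n_a - 1, n_b - 1
    p = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    return VarianceRatioResult(float(f), float(min(p, 1.0)), (dfn, dfd))
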