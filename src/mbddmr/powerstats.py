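"""Phenotype-level statistics: Welch t-test, fold change of group means, and
the power t-test fixing the minimal detectable sperm-count difference.

The power calculation follows the conventional two-sample power t-test: for
per-group size n, common standard deviation sd, two-sided level alpha and
target power 1-beta, the smallest detectable mean difference delta solves

    power(delta) = P(|T'| > t_{1-alpha/2, 2n-2}),   T' ~ nct(2n-2, ncp)

with noncentrality ncp = delta / (sd * sqrt(2/n)). The equal-variance
df = 2n-2 is used for the power solve; Welch-Satterthwaite df is used for
tests on observed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import optimize, stats


@dataclass
class PowerSpec:
    n: int
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class GroupStats:
    mean: float
    sd: float
    n: int


def welch_t_test(a: Union[GroupStats, Sequence[float]],
                 b: Union[GroupStats, Sequence[float]]) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns (t, Welch-Satterthwaite df, two-sided p)."""
    sa = a if isinstance(a, GroupStats) else GroupStats(
        float(np.mean(a)), float(np.std(a, ddof=1)), len(a))
    sb = b if isinstance(b, GroupStats) else GroupStats(
        float(np.mean(b)), float(np.std(b, ddof=1)), len(b))
    if sa.n < 2 or sb.n < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = sa.sd ** 2 / sa.n, sb.sd ** 2 / sb.n
    if va + vb == 0:
        # zero variance in both groups
        if sa.mean == sb.mean:
            return 0.0, float(sa.n + sb.n - 2), 1.0
        return np.inf if sa.mean > sb.mean else -np.inf, float(sa.n + sb.n - 2), 0.0
    t = (sa.mean - sb.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (sa.n - 1) + vb ** 2 / (sb.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def achieved_power(delta: float, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test at mean difference ``delta``."""
    df = 2 * spec.n - 2
    ncp = delta / (spec.sd * np.sqrt(2.0 / spec.n))
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def minimal_detectable_delta(spec: PowerSpec, rtol: float = 1e-6) -> float:
    """Smallest mean difference reaching the requested power (bisection)."""
    hi = spec.sd
    while achieved_power(hi, spec) < spec.power:
        hi *= 2.0
        if hi > 1e6 * spec.sd:
            raise ValueError("requested power unattainable")
    delta = optimize.brentq(
        lambda d: achieved_power(d, spec) - spec.power, 0.0, hi, rtol=rtol)
    return float(delta)


def fold_change(treated_mean: float, control_mean: float) -> float:
    """Ratio treated/control of group means (raw; display-round to one decimal)."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return float(treated_mean) / float(control_mean)


def fold_change_display(treated_mean: float, control_mean: float) -> float:
    return round(fold_change(treated_mean, control_mean), 1)
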