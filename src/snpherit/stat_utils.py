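"""Closed-form statistics for comparing and interpreting estimates.

Small helpers for z-tests between independent estimates, the
probability that a boundary-constrained variance estimator returns
exactly zero, and the large-sample standard error of a regression R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EstimateWithSe:
    """A point estimate with its standard error."""

    estimate: float
    se: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be positive")


def _as_estimate(x) -> EstimateWithSe:
    if isinstance(x, EstimateWithSe):
        return x
    est, se = x
    return EstimateWithSe(float(est), float(se))


def z_diff_test(a, b) -> float:
    """Two-sided normal p-value for a difference of independent estimates.

    z = (a - b) / sqrt(se_a^2 + se_b^2). Assumes the two estimates come
    from non-overlapping samples (a documented caveat otherwise).
    """
    a = _as_estimate(a)
    b = _as_estimate(b)
    z = (a.estimate - b.estimate) / np.hypot(a.se, b.se)
    return float(2.0 * stats.norm.sf(abs(z)))


def z_dev_test(deviation: float, se: float) -> float:
    """Two-sided normal p-value of a deviation against its SE."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(deviation) / se))


def prob_zero_estimate(true_value: float, se: float) -> float:
    """Probability a zero-constrained normal estimator lands exactly at zero.

    Phi(-true_value / se): the mass the unconstrained sampling
    distribution places at or below the boundary.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    return float(stats.norm.cdf(-true_value / se))


def r2_sampling_se(rho2: float, n: int) -> float:
    """Approximate SE of a regression R^2: sqrt(4 rho2 (1 - rho2) / N)."""
    if not 0.0 <= rho2 <= 1.0:
        raise ValueError("rho2 must lie in [0, 1]")
    if n < 2:
        raise ValueError("N must be >= 2")
    return float(np.sqrt(4.0 * rho2 * (1.0 - rho2) / n))
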