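"""Analytic power for Mendelian randomisation with a continuous outcome.

Uses the non-centrality-parameter normal approximation of the mRnd-style
calculation: with sample size *n*, instrument-on-exposure variance fraction
``r2_gx`` and standardised causal effect ``beta_std`` (outcome SDs per
exposure SD), the IV test statistic has NCP = n · r2_gx · beta_std², and the
two-sided power at level α is

    power = 1 − Φ(z_{1−α/2} − √NCP) + Φ(−z_{1−α/2} − √NCP).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerQuery", "mr_ncp", "mr_power", "mr_min_n", "beta_standardised"]


@dataclass
class PowerQuery:
    """Inputs of one power calculation (standardised parameterisation)."""

    n: int
    r2_gx: float
    beta_std: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.n = int(self.n)
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 < self.r2_gx < 1.0:
            raise ValueError("r2_gx must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def beta_standardised(beta_raw: float, sd_exposure: float,
                      sd_outcome: float) -> float:
    """Convert a raw-scale effect to standardised units (β · σ_x / σ_y)."""
    if sd_exposure <= 0 or sd_outcome <= 0:
        raise ValueError("SDs must be positive")
    return beta_raw * sd_exposure / sd_outcome


def mr_ncp(q: PowerQuery) -> float:
    """Non-centrality parameter n · r2_gx · beta_std²."""
    return q.n * q.r2_gx * q.beta_std**2


def mr_power(q: PowerQuery) -> float:
    """Two-sided analytic power of the IV test (normal approximation)."""
    z = norm.ppf(1.0 - q.alpha / 2.0)
    s = mr_ncp(q) ** 0.5
    return float(1.0 - norm.cdf(z - s) + norm.cdf(-z - s))


def mr_min_n(power_target: float, r2_gx: float, beta_std: float,
             alpha: float = 0.05, n_max: int = 10**9) -> int:
    """Smallest integer n reaching the target power, by monotone bisection."""
    if beta_std == 0:
        raise ValueError("beta_std = 0: target power unreachable")
    probe = PowerQuery(2, r2_gx, beta_std, alpha)
    if not probe.alpha < power_target < 1.0:
        raise ValueError("power_target must be in (alpha, 1)")
    lo, hi = 2, 2
    while mr_power(PowerQuery(hi, r2_gx, beta_std, alpha)) < power_target:
        hi *= 2
        if hi > n_max:
            raise ValueError("target power unreachable below n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if mr_power(PowerQuery(mid, r2_gx, beta_std, alpha)) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return lo
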