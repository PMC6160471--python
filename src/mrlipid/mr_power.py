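"""Post-hoc power for binary-outcome two-sample Mendelian randomization.

Uses the standard normal approximation for the causal log odds ratio in a
case-control outcome sample: with total outcome sample size N, case fraction
K and instrument strength r² (fraction of exposure variance explained), the
standard error of the causal log-odds per SD is approximately

    se = 1 / sqrt(N * K * (1-K) * r²)

and the two-sided power at level alpha against an alternative odds ratio
``or_alt`` per SD is

    power = Phi(|ln or_alt|/se - z_{1-alpha/2}) + Phi(-|ln or_alt|/se - z_{1-alpha/2}).

``min_detectable_or`` inverts this for the smallest risk-increasing OR
reaching a target power; the protective counterpart is its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PowerInput", "power_binary", "min_detectable_or"]


@dataclass
class PowerInput:
    """Inputs of the binary-outcome MR power approximation.

    n_outcome : total outcome sample (cases + controls)
    case_fraction : K, cases / n_outcome, in (0, 1)
    r2 : exposure variance explained by the instrument, in (0, 1)
    or_alt : alternative-hypothesis odds ratio per SD of exposure
    alpha : two-sided test level
    """

    n_outcome: float
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0, 1); r2 = 0 gives no instrument")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def power_binary(inp: PowerInput) -> float:
    """Two-sided power of the IVW causal test at the given alternative."""
    se = 1.0 / np.sqrt(inp.n_outcome * inp.case_fraction * (1 - inp.case_fraction) * inp.r2)
    z = stats.norm.ppf(1 - inp.alpha / 2)
    shift = abs(np.log(inp.or_alt)) / se
    return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))


def min_detectable_or(
    n_outcome: float,
    case_fraction: float,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> float:
    """Smallest OR > 1 detectable at ``target_power``, by bisection to 1e-6.

    The symmetric protective bound is the reciprocal of the returned value.
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")

    def gap(log_or: float) -> float:
        inp = PowerInput(n_outcome, case_fraction, r2, float(np.exp(log_or)), alpha)
        return power_binary(inp) - target_power

    hi = 1e-6
    while gap(hi) < 0:  # gap(0) = alpha - target_power < 0, so bracket upward
        hi *= 2.0
        if hi > 50:
            raise ValueError("no detectable OR below exp(50); check inputs")
    log_or = optimize.bisect(gap, 0.0, hi, xtol=1e-6)
    return float(np.exp(log_or))
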