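"""Analytic power for two-sample MR with a binary outcome.

The causal log odds ratio ``b`` is tested with a Wald statistic whose
non-centrality parameter is approximately

    NCP = N * R2 * K * (1 - K) * b**2

where ``N`` is the outcome-study sample size, ``K`` its case fraction, and
``R2`` the exposure variance explained by the instruments.  Two-sided power
at level alpha is ``Phi(sqrt(NCP) - z_{1-alpha/2})`` (the contribution from
the opposite rejection tail is negligible and conventionally dropped); the
minimal detectable odds ratio inverts this in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import ConfigError

__all__ = ["PowerConfig", "mr_power_binary", "detectable_or"]


@dataclass(frozen=True)
class PowerConfig:
    """Study parameters for a binary-outcome power calculation.

    ``n_outcome``: outcome GWAS sample size (cases + controls);
    ``case_fraction``: proportion of cases K; ``r2``: exposure variance
    explained by the instrument; ``alpha``: two-sided test level.
    """

    n_outcome: int
    case_fraction: float
    r2: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome < 1:
            raise ConfigError("n_outcome must be a positive integer")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must be in (0, 1)")
        if self.n_outcome * self.case_fraction < 1:
            raise ConfigError("expected case count below 1")
        if not (0 < self.r2 < 1):
            raise ConfigError("r2 must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    @property
    def ncp_per_b2(self) -> float:
        """NCP per unit squared log odds ratio: N * R2 * K * (1-K)."""
        k = self.case_fraction
        return self.n_outcome * self.r2 * k * (1 - k)


def mr_power_binary(cfg: PowerConfig, odds_ratio: float) -> float:
    """Power to detect a causal effect of the given odds ratio."""
    if not odds_ratio > 0:
        raise ConfigError(f"odds ratio must be positive, got {odds_ratio}")
    b = abs(math.log(odds_ratio))
    z_crit = stats.norm.isf(cfg.alpha / 2)
    return float(stats.norm.cdf(math.sqrt(cfg.ncp_per_b2) * b - z_crit))


def detectable_or(cfg: PowerConfig, target_power: float) -> float:
    """Smallest odds ratio (> 1) detectable at the target power.

    Closed-form inversion: ``b = (z_{1-alpha/2} + z_power) / sqrt(N R2 K(1-K))``.
    """
    if not (0 < target_power < 1):
        raise ConfigError("target_power must be in (0, 1)")
    b = (stats.norm.isf(cfg.alpha / 2) + stats.norm.ppf(target_power)) \
        / math.sqrt(cfg.ncp_per_b2)
    return float(math.exp(b))
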