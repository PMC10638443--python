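"""Statistical power for Mendelian randomisation with a binary outcome,
following the mRnd approach, plus the Bonferroni significance threshold.

The hypothesized odds ratio per unit exposure is attenuated to a
risk-difference-scale effect b = K(OR/(1 + K(OR - 1)) - 1), where K is the
case fraction; the sampling variance of the two-stage estimate is
v = (K(1 - K) - b^2)/(N R^2) with N the outcome sample size and R^2 the total
exposure variance explained by the instruments.  Power is the upper-tail
probability of a non-central chi-square(1, NCP = b^2/v) beyond the central
chi-square (1 - alpha) quantile.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import ValidationError


@dataclass
class PowerParams:
    """Inputs of the binary-outcome power calculation."""

    n: int
    case_fraction: float
    or_hypo: float
    r2_sum: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must be in (0, 1)")
        if not self.or_hypo > 0:
            raise ValidationError("or_hypo must be > 0")
        if not 0.0 < self.r2_sum < 1.0:
            raise ValidationError("r2_sum must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class PowerResult:
    ncp: float
    power: float
    attenuated_beta: float


def binary_outcome_power(params: PowerParams) -> PowerResult:
    """mRnd-style power for detecting ``or_hypo`` at significance ``alpha``."""
    k = params.case_fraction
    b = k * (params.or_hypo / (1.0 + k * (params.or_hypo - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (params.n * params.r2_sum)
    if v <= 0:
        raise ValidationError(
            "degenerate variance: attenuated effect exceeds the outcome variance bound"
        )
    ncp = b * b / v
    crit = stats.chi2.ppf(1.0 - params.alpha, df=1)
    power = float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else params.alpha
    return PowerResult(ncp=float(ncp), power=power, attenuated_beta=float(b))


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test significance threshold alpha / m under Bonferroni correction."""
    if m_tests < 1:
        raise ValidationError(f"m_tests must be >= 1, got {m_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / m_tests
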