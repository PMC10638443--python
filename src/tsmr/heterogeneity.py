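"""Heterogeneity diagnostics and cross-cohort meta-analysis.

Cochran's Q and I^2 are used at two levels with two distinct decision rules:
among the per-SNP Wald ratios within one outcome (heterogeneity flagged at
Q p < 0.05 or I^2 > 25%), and among the per-cohort causal estimates entering
the meta-analysis (random-effects model selected at Q p < 0.1 or I^2 > 50%).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MrEstimate, WaldRatio, Z975
from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: Heterogeneity rule among instruments within one MR analysis.
MR_Q_P_THRESHOLD = 0.05
MR_I2_THRESHOLD = 25.0
#: Heterogeneity rule among cohort estimates in a meta-analysis.
META_Q_P_THRESHOLD = 0.1
META_I2_THRESHOLD = 50.0


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom, upper-tail p and I^2 (%)."""

    q: float
    df: int
    pvalue: float
    i2: float


def _heterogeneity(values: np.ndarray, weights: np.ndarray, pooled: float) -> HeterogeneityResult:
    q = float(np.sum(weights * (values - pooled) ** 2))
    df = len(values) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)), i2=i2)


def cochran_q(
    ratios: Sequence[WaldRatio], pooled_beta: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q among Wald ratios around ``pooled_beta`` (the fixed-effects
    inverse-variance estimate when not supplied), df = n - 1."""
    if len(ratios) < 2:
        raise ValidationError("Cochran's Q requires at least 2 ratios")
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    if pooled_beta is None:
        pooled_beta = float(np.sum(w * r) / np.sum(w))
    return _heterogeneity(r, w, pooled_beta)


def flag_mr_heterogeneity(
    het: HeterogeneityResult,
    p_threshold: float = MR_Q_P_THRESHOLD,
    i2_threshold: float = MR_I2_THRESHOLD,
) -> bool:
    """True when heterogeneity among instruments is assumed (p < 0.05 or I^2 > 25%)."""
    return het.pvalue < p_threshold or het.i2 > i2_threshold


def flag_meta_heterogeneity(
    het: HeterogeneityResult,
    p_threshold: float = META_Q_P_THRESHOLD,
    i2_threshold: float = META_I2_THRESHOLD,
) -> bool:
    """True when heterogeneity among cohort estimates is assumed (p < 0.1 or I^2 > 50%)."""
    return het.pvalue < p_threshold or het.i2 > i2_threshold


@dataclass
class MetaResult:
    """Pooled cross-cohort estimate with heterogeneity footer."""

    model: str  # "fixed" | "random"
    beta_pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    or_pooled: float
    or_ci_low: float
    or_ci_high: float
    pvalue: float
    het: HeterogeneityResult
    tau2: float
    weights_pct: list[float]

    def __post_init__(self) -> None:
        if self.tau2 < 0 or (self.model == "fixed" and self.tau2 != 0):
            raise ValidationError("tau2 must be >= 0 and 0 under the fixed model")


def meta_analyse(
    estimates: Sequence[MrEstimate], model: str = "auto"
) -> MetaResult:
    """Inverse-variance meta-analysis of per-cohort causal estimates.

    ``model='fixed'`` pools with weights 1/se^2; ``model='random'`` uses
    DerSimonian-Laird tau^2 = max(0, (Q - df)/(sum w - sum w^2 / sum w)) and
    weights 1/(se^2 + tau^2); ``model='auto'`` selects random effects iff the
    meta-level heterogeneity rule fires (Q p < 0.1 or I^2 > 50%).
    """
    if len(estimates) < 2:
        raise ValidationError("meta-analysis requires at least 2 estimates")
    b = np.array([e.beta for e in estimates])
    s = np.array([e.se for e in estimates])
    if np.any(s <= 0):
        raise ValidationError("meta-analysis requires positive standard errors")
    w = s**-2.0
    beta_fe = float(np.sum(w * b) / np.sum(w))
    het = _heterogeneity(b, w, beta_fe)
    tau2_dl = max(0.0, (het.q - het.df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    if model == "auto":
        model = "random" if flag_meta_heterogeneity(het) else "fixed"
        log.info("auto-selected %s-effects meta-analysis (Q p = %.3f, I2 = %.0f%%)",
                 model, het.pvalue, het.i2)
    if model == "fixed":
        pooled, se, tau2, w_used = beta_fe, float(np.sum(w) ** -0.5), 0.0, w
    elif model == "random":
        w_star = 1.0 / (s**2 + tau2_dl)
        pooled = float(np.sum(w_star * b) / np.sum(w_star))
        se = float(np.sum(w_star) ** -0.5)
        tau2, w_used = tau2_dl, w_star
    else:
        raise ValidationError(f"unknown meta-analysis model {model!r}")
    p = float(2.0 * stats.norm.sf(abs(pooled) / se))
    lo, hi = pooled - Z975 * se, pooled + Z975 * se
    return MetaResult(
        model=model,
        beta_pooled=pooled,
        se_pooled=se,
        ci_low=float(lo),
        ci_high=float(hi),
        or_pooled=float(np.exp(pooled)),
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
        pvalue=max(p, float(np.finfo(float).tiny)),
        het=het,
        tau2=float(tau2),
        weights_pct=list(100.0 * w_used / np.sum(w_used)),
    )
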