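"""The Mendelian-randomisation estimator battery.

Per-SNP Wald ratios are pooled by inverse-variance weighting (fixed effects
or multiplicative random effects), and complemented by MR-Egger regression
(whose intercept tests directional pleiotropy), the weighted and simple
median estimators (consistent when under half the weight comes from invalid
instruments), a mode-based estimator, and leave-one-out sensitivity analysis.

All pooled effects are on the scale of the outcome beta per unit exposure
(log-odds per SD for a binary outcome); odds ratios are the exponentials.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError
from .summary_io import HarmonizedInstrument

log = logging.getLogger(__name__)

#: Exact 97.5% standard-normal quantile used for every 95% interval.
Z975: float = float(stats.norm.ppf(0.975))

_TINY = np.finfo(float).tiny


@dataclass
class WaldRatio:
    """Per-SNP causal estimate: outcome effect over exposure effect."""

    snp_id: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: Wald ratio se must be > 0")

    @property
    def weight(self) -> float:
        """Inverse-variance weight, exactly se^-2."""
        return self.se**-2


@dataclass
class MrEstimate:
    """A pooled causal estimate on the log-odds scale with its 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_ci_low: float
    or_ci_high: float
    pvalue: float
    n_snps: int

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, n_snps: int, pvalue: float | None = None
    ) -> "MrEstimate":
        lo, hi = beta - Z975 * se, beta + Z975 * se
        if pvalue is None:
            if se > 0:
                pvalue = float(2.0 * stats.norm.sf(abs(beta) / se))
            else:
                pvalue = 1.0 if beta == 0 else 0.0
        pvalue = float(min(max(pvalue, _TINY), 1.0))
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(lo),
            ci_high=float(hi),
            or_value=float(np.exp(beta)),
            or_ci_low=float(np.exp(lo)),
            or_ci_high=float(np.exp(hi)),
            pvalue=pvalue,
            n_snps=n_snps,
        )


@dataclass
class PleiotropyResult:
    """MR-Egger intercept: a test for directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float
    n_snps: int


def wald_ratio(inst: HarmonizedInstrument) -> WaldRatio:
    """Per-SNP ratio beta_out / beta_exp with the first-order delta-method SE
    se_out / |beta_exp| (exposure uncertainty is ignored, as is conventional
    for two-sample summary MR)."""
    if inst.beta_exp == 0:
        raise ValidationError(f"{inst.snp_id}: beta_exp = 0, Wald ratio undefined")
    return WaldRatio(
        snp_id=inst.snp_id,
        ratio=inst.beta_out / inst.beta_exp,
        se=inst.se_out / abs(inst.beta_exp),
    )


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[WaldRatio]:
    return [wald_ratio(i) for i in instruments]


def ivw(ratios: Sequence[WaldRatio], model: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted pooling of Wald ratios.

    ``model='fixed'``: se = (sum of weights)^(-1/2).  ``model='mre'``
    (multiplicative random effects): the fixed-effects SE is scaled by
    sqrt(Q/(n-1)) with *no* lower bound at 1, so under-dispersion shrinks the
    interval.  Point estimates are identical under both models.
    """
    n = len(ratios)
    if n == 0:
        raise ValidationError("ivw requires at least one Wald ratio")
    if model not in ("fixed", "mre"):
        raise ValidationError(f"unknown IVW model {model!r}")
    if model == "mre" and n < 2:
        raise ValidationError("multiplicative random effects needs >= 2 ratios")
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    if n == 1:  # exact identity with the single Wald ratio
        beta, se = float(r[0]), float(ratios[0].se)
    else:
        beta = float(np.sum(w * r) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
    method = "ivw_fe"
    if model == "mre":
        q = float(np.sum(w * (r - beta) ** 2))
        if n == 2:
            warnings.warn("multiplicative random effects with n = 2: Q has a single "
                          "degree of freedom; the scale estimate is unstable")
        se *= np.sqrt(q / (n - 1))
        method = "ivw_mre"
    return MrEstimate.from_beta_se(method, beta, se, n_snps=n)


def egger(instruments: Sequence[HarmonizedInstrument]) -> tuple[MrEstimate, PleiotropyResult]:
    """MR-Egger: weighted least squares of beta_out on beta_exp with a free
    intercept, weights 1/se_out^2, inference on t(n - 2).

    The residual variance estimate scales the standard errors with no floor
    at 1, mirroring the multiplicative-random-effects IVW convention.
    Instruments must be oriented so beta_exp > 0; the intercept estimates the
    average directional pleiotropic effect.
    """
    n = len(instruments)
    if n < 3:
        raise ValidationError("MR-Egger requires at least 3 instruments")
    bx = np.array([i.beta_exp for i in instruments])
    if np.any(bx <= 0):
        raise ValidationError("MR-Egger requires all instruments oriented beta_exp > 0")
    if np.ptp(bx) == 0:
        raise ValidationError("exposure effects are all equal; the Egger slope "
                              "and intercept are not separately identified")
    by = np.array([i.beta_out for i in instruments])
    w = np.array([i.se_out for i in instruments]) ** -2.0
    res = sm.WLS(by, sm.add_constant(bx, has_constant="add"), weights=w).fit()
    slope = MrEstimate.from_beta_se(
        "egger_slope", res.params[1], res.bse[1], n_snps=n, pvalue=float(res.pvalues[1])
    )
    intercept = PleiotropyResult(
        intercept=float(res.params[0]),
        se=float(res.bse[0]),
        pvalue=float(res.pvalues[0]),
        n_snps=n,
    )
    return slope, intercept


def _interpolated_weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation of the 0.5 crossing of the
    cumulative normalized weights minus half each weight."""
    order = np.argsort(r, kind="stable")
    rs, ws = r[order], w[order]
    ws = ws / ws.sum()
    cum = np.cumsum(ws) - 0.5 * ws
    return float(np.interp(0.5, cum, rs))


def _median_estimate(
    ratios: Sequence[WaldRatio],
    weights: np.ndarray,
    method: str,
    n_boot: int,
    seed: int | None,
) -> MrEstimate:
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.se for x in ratios])
    point = _interpolated_weighted_median(r, weights)
    rng = np.random.default_rng(seed)
    draws = r + s * rng.standard_normal((n_boot, r.size))
    boot = np.array([_interpolated_weighted_median(row, weights) for row in draws])
    se = float(np.std(boot, ddof=1))
    return MrEstimate.from_beta_se(method, point, se, n_snps=len(ratios))


def weighted_median(
    ratios: Sequence[WaldRatio], n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median estimator with inverse-variance weights; SE by seeded
    parametric bootstrap (each ratio resampled from Normal(ratio, se))."""
    if len(ratios) < 3:
        raise ValidationError("weighted median requires at least 3 ratios")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    w = np.array([x.weight for x in ratios])
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    return _median_estimate(ratios, w, "weighted_median", n_boot, seed)


def simple_median(
    ratios: Sequence[WaldRatio], n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Equal-weight interpolated median of the Wald ratios."""
    if len(ratios) < 3:
        raise ValidationError("simple median requires at least 3 ratios")
    w = np.ones(len(ratios))
    return _median_estimate(ratios, w, "simple_median", n_boot, seed)


def _mode_bandwidth(r: np.ndarray, bandwidth_factor: float) -> float:
    """Bandwidth for the mode estimator: 0.9 * min(sd, 1.4826 MAD) * n^(-1/5),
    scaled by ``bandwidth_factor``; falls back to the sd when the MAD is zero."""
    sd = float(np.std(r, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    scale = min(sd, mad) if mad > 0 else sd
    return bandwidth_factor * 0.9 * scale * r.size ** (-1 / 5)


def _kde_mode(r: np.ndarray, h: float, grid_size: int = 512) -> float:
    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[np.argmax(dens)])


def simple_mode(
    ratios: Sequence[WaldRatio],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Mode-based estimate: the maximum of a normal-kernel density over the
    unweighted Wald ratios, consistent when the largest cluster of ratios is
    formed by valid instruments (the ZEMPA assumption).  SE by seeded
    parametric bootstrap, re-deriving the bandwidth in each replicate."""
    if len(ratios) < 3:
        raise ValidationError("simple mode requires at least 3 ratios")
    if bandwidth_factor <= 0:
        raise ValidationError("bandwidth_factor must be > 0")
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.se for x in ratios])
    if np.all(r == r[0]):  # degenerate: a point mass has no bandwidth
        return MrEstimate.from_beta_se("simple_mode", float(r[0]), float(s.min()),
                                       n_snps=len(ratios))
    h = _mode_bandwidth(r, bandwidth_factor)
    if h == 0:
        raise ValidationError("zero bandwidth; ratios are degenerate")
    point = _kde_mode(r, h)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rb = r + s * rng.standard_normal(r.size)
        hb = _mode_bandwidth(rb, bandwidth_factor)
        boot[b] = _kde_mode(rb, hb) if hb > 0 else float(np.median(rb))
    se = float(np.std(boot, ddof=1))
    return MrEstimate.from_beta_se("simple_mode", point, se, n_snps=len(ratios))


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument], method: str = "ivw_mre"
) -> list[tuple[str, MrEstimate]]:
    """Re-estimate with each instrument excluded in turn.

    ``method`` is ``'ivw_mre'`` or ``'ivw_fe'``.  When a single instrument
    remains the fixed-effects pooling (identical to its Wald ratio) is used.
    """
    if len(instruments) < 2:
        raise ValidationError("leave-one-out requires at least 2 instruments")
    model = {"ivw_mre": "mre", "ivw_fe": "fixed"}.get(method)
    if model is None:
        raise ValidationError(f"unsupported leave-one-out method {method!r}")
    out = []
    for i, excluded in enumerate(instruments):
        rest = [inst for j, inst in enumerate(instruments) if j != i]
        ratios = wald_ratios(rest)
        use_model = model if len(ratios) >= 2 else "fixed"
        out.append((excluded.snp_id, ivw(ratios, model=use_model)))
    return out


def all_estimates(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    bandwidth_factor: float = 1.0,
) -> list[MrEstimate]:
    """The full battery in report order: IVW fixed, IVW multiplicative random
    effects, weighted median, simple median, simple mode, Egger slope."""
    ratios = wald_ratios(instruments)
    seed_seq = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(3)]
    ests = [
        ivw(ratios, model="fixed"),
        ivw(ratios, model="mre"),
        weighted_median(ratios, n_boot=n_boot, seed=seeds[0]),
        simple_median(ratios, n_boot=n_boot, seed=seeds[1]),
        simple_mode(ratios, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seeds[2]),
    ]
    slope, _ = egger(instruments)
    ests.append(slope)
    return ests
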