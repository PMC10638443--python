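"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator follows the linear instrument -> exposure -> outcome model
underlying summary-data Mendelian randomisation: SNP j with allele frequency
p_j has true effect gamma_j on the (standardised) exposure and direct
pleiotropic effect alpha_j on the outcome log-odds, so the outcome effect is
beta_star * gamma_j + alpha_j.  Sampling errors use the standard score-test
variances: se_x = (2 p (1-p) N_x)^(-1/2) for a variance-1 continuous
exposure and se_y = (2 p (1-p) N_y K (1-K))^(-1/2) for a binary outcome with
case fraction K.  Pleiotropy is independent of instrument strength by
construction, so the InSIDE assumption holds.

Defaults mirror the uridine/atrial-fibrillation setting: exposure GWAS of
7,824, outcome GWAS of 1,030,836 with K = 60,620/1,030,836, and instruments
each explaining roughly 3-8% of exposure variance, as metabolite loci do.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .instruments import LdMatrix
from .summary_io import GwasAssociation, SummarySet

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated two-sample dataset."""

    n_snps: int = 50
    n_exposure: int = 7824
    n_outcome: int = 1_030_836
    case_fraction: float = 60_620 / 1_030_836
    causal_beta: float = -1.3
    gamma_mean: float = 0.4
    gamma_sd: float = 0.1
    gamma_min_abs: float = 0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValidationError("sample sizes must be >= 2")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must be in (0, 1)")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ValidationError("sd parameters must be >= 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("eaf_range must lie within (0, 1)")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValidationError("invalid_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated SNP; valid instruments have alpha = 0."""

    snp_id: str
    true_gamma: float
    true_alpha: float
    is_valid: bool


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.finfo(float).tiny)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummarySet, SummarySet, list[TruthRecord]]:
    """Draw one exposure set, one outcome set and the truth records.

    The same seed yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    eaf = rng.uniform(*config.eaf_range, n)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, n)
    # enforce the minimum instrument strength without changing the sign
    signs = np.where(gamma >= 0, 1.0, -1.0)
    gamma = signs * np.maximum(np.abs(gamma), config.gamma_min_abs)
    invalid = rng.random(n) < config.invalid_fraction
    alpha = np.where(
        invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n), 0.0
    )
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), n)

    se_x = (2.0 * eaf * (1.0 - eaf) * config.n_exposure) ** -0.5
    beta_x = rng.normal(gamma, se_x)
    k = config.case_fraction
    se_y = (2.0 * eaf * (1.0 - eaf) * config.n_outcome * k * (1.0 - k)) ** -0.5
    beta_y = rng.normal(config.causal_beta * gamma + alpha, se_y)
    p_x = _two_sided_p(beta_x, se_x)
    p_y = _two_sided_p(beta_y, se_y)

    n_cases = int(round(k * config.n_outcome))
    exp_records, out_records, truths = [], [], []
    for j in range(n):
        sid = f"snp{j + 1:04d}"
        ea, oa = _ALLELE_PAIRS[allele_idx[j]]
        exp_records.append(
            GwasAssociation(sid, ea, oa, float(eaf[j]), float(beta_x[j]),
                            float(se_x[j]), float(p_x[j]), n=config.n_exposure,
                            chrom="1", pos=(j + 1) * 1_000_000)
        )
        out_records.append(
            GwasAssociation(sid, ea, oa, float(eaf[j]), float(beta_y[j]),
                            float(se_y[j]), float(p_y[j]), n=config.n_outcome,
                            n_cases=n_cases, chrom="1", pos=(j + 1) * 1_000_000)
        )
        truths.append(
            TruthRecord(sid, float(gamma[j]), float(alpha[j]), bool(alpha[j] == 0.0))
        )
    exposure = SummarySet.from_records(
        "sim_exposure", "continuous", exp_records, n_default=config.n_exposure
    )
    outcome = SummarySet.from_records(
        "sim_outcome", "binary", out_records,
        n_default=config.n_outcome, n_cases_default=n_cases,
    )
    return exposure, outcome, truths


def generate_clump_instance(
    block_sizes: Sequence[int],
    within_r2: float | Sequence[float] = 0.9,
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 5000,
) -> tuple[SummarySet, LdMatrix]:
    """A SummarySet and block-diagonal LD matrix for exercising clumping.

    SNPs sit ``spacing_bp`` apart on one chromosome; within each block every
    off-diagonal LD r^2 equals the block's ``within_r2``; across blocks LD
    is zero.  P-values are drawn log-uniformly below genome-wide significance.
    """
    if not block_sizes or any(b < 1 for b in block_sizes):
        raise ValidationError("block sizes must be positive")
    n = int(sum(block_sizes))
    r2s = (
        list(within_r2)
        if isinstance(within_r2, (list, tuple, np.ndarray))
        else [float(within_r2)] * len(block_sizes)
    )
    if len(r2s) != len(block_sizes):
        raise ValidationError("one within_r2 per block required")
    rng = np.random.default_rng(seed)
    pvals = 10.0 ** rng.uniform(-12, -8.31, n)
    eaf = rng.uniform(0.1, 0.9, n)
    records = [
        GwasAssociation(
            f"snp{j + 1:04d}", "A", "G", float(eaf[j]), 0.1, 0.01, float(pvals[j]),
            chrom=chrom, pos=(j + 1) * spacing_bp,
        )
        for j in range(n)
    ]
    m = np.eye(n)
    start = 0
    for size, r2 in zip(block_sizes, r2s):
        block = slice(start, start + size)
        sub = np.full((size, size), r2)
        np.fill_diagonal(sub, 1.0)
        m[block, block] = sub
        start += size
    sset = SummarySet.from_records("sim_clump", "continuous", records)
    return sset, LdMatrix([r.snp_id for r in records], m)
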