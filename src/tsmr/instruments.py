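"""Instrument selection and quality control.

Covers the standard screening steps that turn a list of exposure-associated
SNPs into a set of valid instrumental variables: genome-wide significance
filtering, greedy LD clumping, variance explained (R^2), the F-statistic for
weak-instrument bias, a minor-allele-frequency check, and Steiger
directionality filtering against reverse causation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .summary_io import GwasAssociation, HarmonizedInstrument, SummarySet

log = logging.getLogger(__name__)


@dataclass
class InstrumentStrength:
    """Variance explained and F-statistic of one instrument."""

    snp_id: str
    r2: float
    f_stat: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 < 1.0:
            raise ValidationError(f"{self.snp_id}: r2 must be in [0, 1), got {self.r2}")
        if self.f_stat < 0:
            raise ValidationError(f"{self.snp_id}: f_stat must be >= 0")


@dataclass
class SteigerResult:
    """Directionality of one instrument: variance explained in exposure vs outcome."""

    snp_id: str
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_p: float


@dataclass
class LdMatrix:
    """Symmetric pairwise LD r^2 matrix with unit diagonal."""

    snp_ids: list[str]
    r2_values: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.r2_values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.snp_ids):
            raise ValidationError("LD matrix must be square and match snp_ids")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self.r2_values = m
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LdMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def get(self, a: str, b: str) -> float | None:
        """Pairwise r^2, or None when either SNP is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2_values[ia, ib])


def read_ld_matrix(path: str | Path, sep: str = "\t") -> LdMatrix:
    """Read a square LD matrix (SNP ids as header row and first column)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LdMatrix(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def read_ld_long(path: str | Path, sep: str = "\t") -> LdMatrix:
    """Read long-format LD (columns snp_a, snp_b, r2) into a matrix."""
    df = pd.read_csv(path, sep=sep)
    ids = sorted(set(df["snp_a"].astype(str)) | set(df["snp_b"].astype(str)))
    idx = {s: i for i, s in enumerate(ids)}
    m = np.eye(len(ids))
    for r in df.itertuples(index=False):
        i, j = idx[str(r.snp_a)], idx[str(r.snp_b)]
        m[i, j] = m[j, i] = float(r.r2)
    return LdMatrix(ids, m)


def filter_by_pvalue(sset: SummarySet, threshold: float = 5e-8) -> SummarySet:
    """Retain records with association p strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(f"p-value threshold must be in (0, 1], got {threshold}")
    keep = [sid for sid, rec in sset.records.items() if rec.pvalue < threshold]
    dropped = len(sset) - len(keep)
    if dropped:
        log.info("p-value filter at %g: excluded %d of %d SNPs", threshold, dropped, len(sset))
    return sset.subset(keep)


def ld_clump(
    sset: SummarySet,
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SummarySet:
    """Greedy p-value-ordered LD clumping.

    Repeatedly accepts the most significant remaining SNP as an index and
    removes all other candidates on the same chromosome within ``window_kb``
    kilobases (centre to centre) whose LD r^2 with the index exceeds
    ``r2_threshold``.  SNP pairs absent from the LD matrix are treated as
    independent and logged.
    """
    order = sorted(sset.records.values(), key=lambda r: r.pvalue)
    accepted: list[str] = []
    removed: set[str] = set()
    window_bp = window_kb * 1000.0
    for idx_rec in order:
        if idx_rec.snp_id in removed:
            continue
        accepted.append(idx_rec.snp_id)
        for other in order:
            if other.snp_id in removed or other.snp_id in accepted:
                continue
            if idx_rec.chrom is None or other.chrom is None or idx_rec.chrom != other.chrom:
                continue
            if idx_rec.pos is None or other.pos is None:
                continue
            if abs(idx_rec.pos - other.pos) > window_bp:
                continue
            r2 = ld.get(idx_rec.snp_id, other.snp_id) if ld is not None else None
            if r2 is None:
                log.warning("LD for pair (%s, %s) unavailable; treated as independent",
                            idx_rec.snp_id, other.snp_id)
                continue
            if r2 > r2_threshold:
                removed.add(other.snp_id)
    log.info("clumping retained %d of %d SNPs", len(accepted), len(sset))
    return sset.subset(accepted)


def variance_explained(
    assoc: GwasAssociation, n: int, formula: str = "printed"
) -> float:
    """Proportion of exposure variance explained by one SNP.

    ``formula='printed'`` follows the manuscript's formula

        R^2 = 2 EAF (1-EAF) beta^2 /
              (2 EAF (1-EAF) beta^2 + 2 EAF (1-EAF) se N beta^2)

    which algebraically reduces to 1 / (1 + se * N): the EAF and beta terms
    cancel.  ``formula='standard'`` uses the conventional expression with
    se^2 * N in the denominator, i.e. beta^2 / (beta^2 + N se^2).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if assoc.beta == 0:
        raise ValidationError(f"{assoc.snp_id}: beta = 0 leaves R^2 undefined")
    if not 0.0 < assoc.eaf < 1.0:
        raise ValidationError(f"{assoc.snp_id}: eaf must be strictly inside (0, 1)")
    num = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
    if formula == "printed":
        den = num + 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.se * n * assoc.beta**2
    elif formula == "standard":
        den = num + 2.0 * assoc.eaf * (1.0 - assoc.eaf) * n * assoc.se**2
    else:
        raise ConfigurationError(f"unknown R^2 formula {formula!r}")
    return num / den


def f_statistic(r2: float, n: int, k: int) -> float:
    """F-statistic for weak-instrument bias: F = R^2 (N - k - 1) / (1 - R^2)."""
    if not 0.0 <= r2 < 1.0:
        raise ValidationError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1 (n={n}, k={k})")
    return r2 * (n - k - 1) / (1.0 - r2)


def instrument_strengths(
    sset: SummarySet, n: int | None = None, formula: str = "printed"
) -> list[InstrumentStrength]:
    """Per-SNP R^2 and F for every record, with k = number of instruments."""
    k = len(sset)
    out = []
    for rec in sset:
        n_i = rec.n if rec.n is not None else (n if n is not None else sset.n_default)
        if n_i is None:
            raise ConfigurationError(f"{rec.snp_id}: no sample size available")
        r2 = variance_explained(rec, n_i, formula=formula)
        out.append(InstrumentStrength(rec.snp_id, r2, f_statistic(r2, n_i, k), n_i, k))
    return out


def weak_instrument_filter(
    strengths: Sequence[InstrumentStrength], f_min: float = 10.0
) -> list[str]:
    """Ids of instruments with F >= ``f_min``; weaker ones are dropped and logged."""
    if not f_min > 0:
        raise ConfigurationError(f"f_min must be > 0, got {f_min}")
    kept = [s.snp_id for s in strengths if s.f_stat >= f_min]
    for s in strengths:
        if s.f_stat < f_min:
            log.info("%s removed as weak instrument (F = %.2f < %g)", s.snp_id, s.f_stat, f_min)
    return kept


def maf_check(sset: SummarySet, maf_min: float = 0.01) -> list[str]:
    """Ids of SNPs whose minor allele frequency falls below ``maf_min``."""
    if not 0.0 < maf_min < 0.5:
        raise ConfigurationError(f"maf_min must be in (0, 0.5), got {maf_min}")
    flagged = [rec.snp_id for rec in sset if rec.maf < maf_min]
    for sid in flagged:
        log.warning("%s flagged: MAF %.4f below %g", sid, sset[sid].maf, maf_min)
    return flagged


def _r2_from_summary(beta: float, se: float, n: int) -> float:
    """Squared trait-SNP correlation from the test statistic: r^2 = t^2/(t^2 + n - 2)."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def _liability_factor(case_fraction: float) -> float:
    """Observed-scale to liability-scale conversion K(1-K)/phi(z_K)^2."""
    z = stats.norm.ppf(case_fraction)
    return case_fraction * (1.0 - case_fraction) / stats.norm.pdf(z) ** 2


def steiger_filter(
    instruments: Sequence[HarmonizedInstrument],
    n_exp: int,
    n_out: int,
    outcome_type: str = "binary",
    case_fraction: float | None = None,
) -> list[SteigerResult]:
    """Per-SNP Steiger directionality test.

    The SNP-trait correlation in each sample is recovered from the summary
    test statistic via r^2 = t^2 / (t^2 + n - 2).  For a binary outcome the
    observed-scale r^2 is converted to the liability scale by the factor
    K(1-K)/phi(Phi^{-1}(K))^2, where K is the case fraction, so that exposure
    and outcome correlations are compared on a common continuous scale.  The
    p-value is a two-sided Fisher z-test on the difference of the two
    (independent-sample) correlations.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValidationError("Steiger filtering needs sample sizes > 3")
    if outcome_type not in ("continuous", "binary"):
        raise ConfigurationError(f"unknown outcome_type {outcome_type!r}")
    if outcome_type == "binary":
        if case_fraction is None or not 0.0 < case_fraction < 1.0:
            raise ConfigurationError("binary outcome requires case_fraction in (0, 1)")
        factor = _liability_factor(case_fraction)
    results = []
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    for inst in instruments:
        r2_exp = _r2_from_summary(inst.beta_exp, inst.se_exp, n_exp)
        r2_out = _r2_from_summary(inst.beta_out, inst.se_out, n_out)
        if outcome_type == "binary":
            r2_out = min(r2_out * factor, 1.0 - 1e-12)
        z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / denom
        results.append(
            SteigerResult(
                snp_id=inst.snp_id,
                r2_exposure=r2_exp,
                r2_outcome=r2_out,
                correct_direction=bool(r2_exp > r2_out),
                steiger_p=float(2.0 * stats.norm.sf(abs(z))),
            )
        )
    return results


def apply_exclusion_list(sset: SummarySet, exclude: Sequence[str]) -> SummarySet:
    """Drop user-supplied SNP ids (e.g. confounder-associated variants)."""
    excluded = [sid for sid in exclude if sid in sset]
    for sid in excluded:
        log.info("%s removed via exclusion list", sid)
    return sset.subset([sid for sid in sset.records if sid not in set(exclude)])


def read_exclusion_list(path: str | Path) -> list[str]:
    """Plain-text exclusion list: one rsID per line, blank lines ignored."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
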