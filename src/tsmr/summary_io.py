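"""Reading, validating and harmonizing GWAS summary statistics.

Two-sample Mendelian randomisation starts from per-SNP association records in
an exposure GWAS and one or more outcome GWAS.  Before any estimator runs the
two sets must be *harmonized*: aligned to a common effect allele, with strand
flips recoded, ambiguous palindromic variants removed, and every instrument
oriented so that the exposure effect is positive (regression-based estimators
such as MR-Egger require a consistent orientation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, NoSharedInstrumentsError, ValidationError

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default header names for delimited summary-statistics files.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "chrom": "chrom",
    "pos": "pos",
    "n": "n",
    "n_cases": "ncase",
}
_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")
_OPTIONAL_FIELDS = ("chrom", "pos", "n", "n_cases")


@dataclass
class GwasAssociation:
    """One SNP's summary statistics in one GWAS.

    ``beta`` is the per-effect-allele estimate: SD units for continuous
    traits, log-odds for binary traits.  Alleles are upper-cased single
    nucleotides; indels and multi-allelic records are rejected.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single nucleotides, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.n is not None and self.n < 1:
            raise ValidationError(f"{self.snp_id}: n must be >= 1, got {self.n}")
        if self.n_cases is not None and self.n is not None and self.n_cases > self.n:
            raise ValidationError(f"{self.snp_id}: n_cases exceeds n")

    @property
    def maf(self) -> float:
        """Minor allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def palindromic(self) -> bool:
        """True for A/T and C/G pairs, whose strand cannot be resolved from alleles."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flip_allele(self) -> "GwasAssociation":
        """Report the same association with the allele roles swapped."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class SummarySet:
    """A named collection of :class:`GwasAssociation`, unique by ``snp_id``."""

    trait: str
    trait_type: str  # "continuous" | "binary"
    records: dict[str, GwasAssociation] = field(default_factory=dict)
    n_default: int | None = None
    n_cases_default: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"trait_type must be continuous|binary, got {self.trait_type}")

    @classmethod
    def from_records(cls, trait, trait_type, records: Sequence[GwasAssociation], **kw) -> "SummarySet":
        mapping: dict[str, GwasAssociation] = {}
        for rec in records:
            if rec.snp_id in mapping:
                raise ValidationError(f"duplicate snp_id {rec.snp_id} in set {trait}")
            mapping[rec.snp_id] = rec
        return cls(trait=trait, trait_type=trait_type, records=mapping, **kw)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GwasAssociation]:
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> GwasAssociation:
        return self.records[snp_id]

    def sample_size(self, snp_id: str) -> int | None:
        """Per-SNP sample size, falling back to the set-level default."""
        n = self.records[snp_id].n
        return n if n is not None else self.n_default

    def subset(self, snp_ids: Sequence[str]) -> "SummarySet":
        """A new set restricted to ``snp_ids``, preserving this set's order."""
        keep = set(snp_ids)
        return SummarySet(
            trait=self.trait,
            trait_type=self.trait_type,
            records={sid: rec for sid, rec in self.records.items() if sid in keep},
            n_default=self.n_default,
            n_cases_default=self.n_cases_default,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            rows.append(
                {
                    "SNP": rec.snp_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "effect_allele": rec.effect_allele,
                    "other_allele": rec.other_allele,
                    "eaf": rec.eaf,
                    "beta": rec.beta,
                    "se": rec.se,
                    "pval": rec.pvalue,
                    "n": rec.n,
                    "ncase": rec.n_cases,
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome associations aligned to a common effect allele.

    After harmonization ``beta_exp > 0`` for every instrument (the whole
    record is re-oriented when the exposure effect was negative), ``flipped``
    records whether the outcome alleles had to be swapped to match the
    exposure, and ``palindromic`` marks A/T and C/G variants that survived
    the ambiguity window.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not self.se_exp > 0 or not self.se_out > 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be > 0")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait: str | None = None,
    n_default: int | None = None,
    n_cases_default: int | None = None,
    sep: str = "\t",
) -> SummarySet:
    """Read delimited summary statistics into a :class:`SummarySet`.

    ``column_map`` maps field names (``snp_id``, ``beta``, ...) to header
    names in the file; unmapped fields use :data:`DEFAULT_COLUMNS`.  Rows with
    missing or non-numeric beta/se, or violating record invariants, are
    rejected with a logged reason; accepted/rejected counts are logged.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [cols[f] for f in _REQUIRED_FIELDS if cols[f] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mapped column(s) {missing}")

    records: list[GwasAssociation] = []
    rejected = 0
    for idx, row in df.iterrows():
        try:
            beta = float(row[cols["beta"]])
            se = float(row[cols["se"]])
            if pd.isna(beta) or pd.isna(se):
                raise ValueError("missing beta/se")
            kwargs: dict = {}
            for f in _OPTIONAL_FIELDS:
                col = cols[f]
                if col in df.columns and not pd.isna(row[col]):
                    if f == "chrom":
                        kwargs[f] = str(row[col])
                    else:
                        kwargs[f] = int(row[col])
            rec = GwasAssociation(
                snp_id=str(row[cols["snp_id"]]),
                effect_allele=str(row[cols["effect_allele"]]),
                other_allele=str(row[cols["other_allele"]]),
                eaf=float(row[cols["eaf"]]),
                beta=beta,
                se=se,
                pvalue=float(row[cols["pvalue"]]),
                **kwargs,
            )
        except (ValueError, ValidationError) as exc:
            rejected += 1
            log.warning("%s row %d rejected: %s", path.name, idx, exc)
            continue
        records.append(rec)
    sset = SummarySet.from_records(
        trait=trait or path.stem,
        trait_type=trait_type,
        records=records,
        n_default=n_default,
        n_cases_default=n_cases_default,
    )
    log.info("%s: accepted %d rows, rejected %d", path.name, len(records), rejected)
    return sset


def _match_alleles(exp: GwasAssociation, out: GwasAssociation) -> bool | None:
    """Return False (aligned), True (swapped) or None (incompatible).

    Tries the outcome alleles as reported, then their strand complement.
    """
    pairs = [(out.effect_allele, out.other_allele)]
    comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if comp != pairs[0]:
        pairs.append(comp)
    for ea, oa in pairs:
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            return False
        if (ea, oa) == (exp.other_allele, exp.effect_allele):
            return True
    return None


def harmonize(
    exposure: SummarySet,
    outcome: SummarySet,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align exposure and outcome records to a common effect allele.

    Intersects on ``snp_id``; flips the outcome beta sign (and complements the
    frequency) when its alleles are reported the other way round; recodes
    strand-complement pairs before matching; drops palindromic SNPs whose
    minor allele frequency lies within ``palindrome_eaf_window`` of 0.5 (the
    strand is then unresolvable); and finally orients every instrument so
    ``beta_exp > 0``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise NoSharedInstrumentsError("one of the summary sets is empty")
    shared = [sid for sid in exposure.records if sid in outcome]
    if not shared:
        raise NoSharedInstrumentsError(
            f"no shared instruments between {exposure.trait!r} and {outcome.trait!r}"
        )
    instruments: list[HarmonizedInstrument] = []
    for sid in shared:
        exp, out = exposure[sid], outcome[sid]
        swapped = _match_alleles(exp, out)
        if swapped is None:
            log.warning("%s: outcome alleles %s/%s incompatible with exposure %s/%s; dropped",
                        sid, out.effect_allele, out.other_allele,
                        exp.effect_allele, exp.other_allele)
            continue
        if exp.palindromic and (0.5 - exp.maf) <= palindrome_eaf_window:
            log.warning("%s: palindromic with MAF %.3f within %.2f of 0.5; dropped",
                        sid, exp.maf, palindrome_eaf_window)
            continue
        beta_out = -out.beta if swapped else out.beta
        beta_exp, eaf_exp = exp.beta, exp.eaf
        ea, oa = exp.effect_allele, exp.other_allele
        if beta_exp < 0:  # orient so the exposure-increasing allele is the effect allele
            beta_exp, beta_out = -beta_exp, -beta_out
            eaf_exp = 1.0 - eaf_exp
            ea, oa = oa, ea
        instruments.append(
            HarmonizedInstrument(
                snp_id=sid,
                effect_allele=ea,
                other_allele=oa,
                beta_exp=beta_exp,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=eaf_exp,
                flipped=bool(swapped),
                palindromic=exp.palindromic,
            )
        )
    log.info("harmonized %d/%d shared instruments (%s vs %s)",
             len(instruments), len(shared), exposure.trait, outcome.trait)
    return instruments


_HARMONIZED_COLUMNS = [
    "SNP", "effect_allele", "other_allele", "eaf_exp",
    "beta_exp", "se_exp", "beta_out", "se_out", "flipped", "palindromic",
]


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path: str | Path) -> None:
    """Write harmonized instruments as TSV; round-trips losslessly through
    :func:`read_harmonized` (floats use shortest round-trip representation)."""
    if not instruments:
        raise ValidationError("cannot write an empty instrument collection")
    rows = [
        {
            "SNP": i.snp_id,
            "effect_allele": i.effect_allele,
            "other_allele": i.other_allele,
            # repr() is the shortest representation that round-trips exactly
            "eaf_exp": repr(i.eaf_exp),
            "beta_exp": repr(i.beta_exp),
            "se_exp": repr(i.se_exp),
            "beta_out": repr(i.beta_out),
            "se_out": repr(i.se_out),
            "flipped": i.flipped,
            "palindromic": i.palindromic,
        }
        for i in instruments
    ]
    pd.DataFrame(rows, columns=_HARMONIZED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | Path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _HARMONIZED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing harmonized column(s) {missing}")
    return [
        HarmonizedInstrument(
            snp_id=str(r.SNP),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
            beta_exp=float(r.beta_exp),
            se_exp=float(r.se_exp),
            beta_out=float(r.beta_out),
            se_out=float(r.se_out),
            eaf_exp=float(r.eaf_exp),
            flipped=bool(r.flipped),
            palindromic=bool(r.palindromic),
        )
        for r in df.itertuples(index=False)
    ]
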