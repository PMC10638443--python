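"""The embedded uridine/atrial-fibrillation instrument table.

Three SNPs instrument plasma uridine (Metabolomics GWAS server, 7,824
European participants; betas in SD units), with their log-odds associations
with atrial fibrillation in three independent outcome GWAS: the Nielsen et
al. meta-analysis (1,030,836 participants, 60,620 cases), the Atrial
Fibrillation Haplotype Reference Consortium (AF HRC; 588,190 / 65,446) and
FinnGen (164,491 / 28,670).  These published per-SNP summary statistics are
the package's reference analysis input.
"""
from __future__ import annotations

from .summary_io import GwasAssociation, SummarySet

EXPOSURE_N = 7824

#: Outcome dataset label -> (total sample size, case count).
OUTCOME_SIZES: dict[str, tuple[int, int]] = {
    "nielsen": (1_030_836, 60_620),
    "af_hrc": (588_190, 65_446),
    "finngen": (164_491, 28_670),
}

# snp_id: (chrom, pos, effect allele, other allele, EAF)
_VARIANTS = {
    "rs2686796": ("7", 48_102_911, "T", "C", 0.4524),
    "rs532545": ("1", 20_915_172, "T", "C", 0.3065),
    "rs7626692": ("2", 50_943_423, "A", "G", 0.2043),
}

# snp_id: (beta, se, p) for uridine (SD units) and each AF dataset (log-odds).
_EXPOSURE = {
    "rs2686796": (0.0094, 0.0017, 1.89e-8),
    "rs532545": (-0.0095, 0.0017, 3.41e-8),
    "rs7626692": (0.0112, 0.0019, 1.21e-9),
}
_OUTCOMES = {
    "nielsen": {
        "rs2686796": (-0.0074, 0.0067, 0.269),
        "rs532545": (0.0158, 0.0071, 0.026),
        "rs7626692": (-0.0171, 0.0085, 0.044),
    },
    "af_hrc": {
        "rs2686796": (-0.0142, 0.0072, 0.048),
        "rs532545": (0.0186, 0.0077, 0.015),
        "rs7626692": (-0.0052, 0.0096, 0.588),
    },
    "finngen": {
        "rs2686796": (-0.0285, 0.0149, 0.055),
        "rs532545": (-0.0385, 0.0183, 0.035),
        "rs7626692": (-0.0137, 0.0209, 0.512),
    },
}


def table2_fixture() -> tuple[SummarySet, dict[str, SummarySet]]:
    """The uridine exposure set and the three AF outcome sets."""
    exp_records = []
    for sid, (chrom, pos, ea, oa, eaf) in _VARIANTS.items():
        beta, se, p = _EXPOSURE[sid]
        exp_records.append(
            GwasAssociation(sid, ea, oa, eaf, beta, se, p,
                            n=EXPOSURE_N, chrom=chrom, pos=pos)
        )
    exposure = SummarySet.from_records(
        "uridine", "continuous", exp_records, n_default=EXPOSURE_N
    )
    outcomes: dict[str, SummarySet] = {}
    for label, rows in _OUTCOMES.items():
        n_total, n_cases = OUTCOME_SIZES[label]
        recs = []
        for sid, (beta, se, p) in rows.items():
            chrom, pos, ea, oa, eaf = _VARIANTS[sid]
            recs.append(
                GwasAssociation(sid, ea, oa, eaf, beta, se, p,
                                n=n_total, n_cases=n_cases, chrom=chrom, pos=pos)
            )
        outcomes[label] = SummarySet.from_records(
            f"atrial_fibrillation_{label}", "binary", recs,
            n_default=n_total, n_cases_default=n_cases,
        )
    return exposure, outcomes
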