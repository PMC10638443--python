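"""Configuration-driven end-to-end two-sample MR analysis.

Runs instrument selection, clumping, QC, Steiger filtering, harmonization,
the estimator battery, heterogeneity/pleiotropy diagnostics and
leave-one-out per outcome, then a cross-cohort meta-analysis — and emits the
results as machine-readable tables (TSV) plus a JSON bundle.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators, fixtures, heterogeneity, instruments, power, summary_io
from .exceptions import ConfigurationError, PipelineError

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and inputs of one pipeline run.

    ``exposure`` and outcome paths may be the literal string ``"fixture"`` to
    use the embedded uridine/atrial-fibrillation tables.
    """

    exposure: str = "fixture"
    outcomes: dict[str, str] = field(default_factory=lambda: {"fixture": "fixture"})
    exposure_columns: dict[str, str] | None = None
    outcome_columns: dict[str, str] | None = None
    ld_matrix: str | None = None
    exclude_snps: list[str] = field(default_factory=list)
    n_exposure: int | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    f_min: float = 10.0
    maf_min: float = 0.01
    palindrome_eaf_window: float = 0.08
    r2_formula: str = "printed"
    primary_method: str = "ivw_mre"
    n_boot: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    n_tests: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb < 0 or self.f_min <= 0:
            raise ConfigurationError("clump_window_kb must be >= 0 and f_min > 0")
        if not 0.0 < self.maf_min < 0.5:
            raise ConfigurationError("maf_min must be in (0, 0.5)")
        if self.primary_method not in ("ivw_mre", "ivw_fe"):
            raise ConfigurationError("primary_method must be ivw_mre or ivw_fe")
        if self.n_tests < 1 or not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("invalid alpha / n_tests")
        if self.seed is None:
            raise ConfigurationError(
                "seed is required: the median/mode bootstrap is stochastic"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls(**dict(raw))


def _fmt_or(x: float) -> str:
    return f"{x:.2f}"


def _fmt_p(x: float) -> str:
    return f"{x:.3g}"


def _load_inputs(config: AnalysisConfig):
    if config.exposure == "fixture" or any(
        p == "fixture" for p in config.outcomes.values()
    ):
        fx_exp, fx_out = fixtures.table2_fixture()
    if config.exposure == "fixture":
        exposure = fx_exp
        outcomes = {}
        for label, path in config.outcomes.items():
            if path == "fixture":
                outcomes = dict(fx_out)
                break
            outcomes[label] = summary_io.read_summary_stats(
                path, column_map=config.outcome_columns, trait_type="binary", trait=label
            )
    else:
        exposure = summary_io.read_summary_stats(
            config.exposure,
            column_map=config.exposure_columns,
            trait_type="continuous",
            n_default=config.n_exposure,
        )
        outcomes = {
            label: (
                fx_out[label]
                if path == "fixture"
                else summary_io.read_summary_stats(
                    path, column_map=config.outcome_columns, trait_type="binary", trait=label
                )
            )
            for label, path in config.outcomes.items()
        }
    if config.n_exposure is not None:
        exposure.n_default = config.n_exposure
    return exposure, outcomes


def run_pipeline(
    config: AnalysisConfig, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the full analysis and return a bundle of result tables.

    The bundle maps table names (``instruments``, ``estimates``,
    ``diagnostics``, ``meta``, ``scatter``, ``scatter_lines``, ``loo``) to
    DataFrames, plus ``power`` (a one-row DataFrame) and ``bonferroni``.
    When ``out_dir`` is given every table is written as TSV alongside a JSON
    bundle; re-running with identical config and seed reproduces the files
    byte for byte.
    """
    stage = "load"
    try:
        exposure, outcomes = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError(stage, str(exc)) from exc

    # --- instrument selection -------------------------------------------
    stage = "selection"
    selected = instruments.filter_by_pvalue(exposure, config.p_threshold)
    if len(selected) == 0:
        raise PipelineError(stage, "no instruments remain after the p-value filter")

    stage = "clumping"
    try:
        ld = (
            instruments.read_ld_matrix(config.ld_matrix)
            if config.ld_matrix
            else None
        )
        clumped = instruments.ld_clump(
            selected, ld, r2_threshold=config.clump_r2, window_kb=config.clump_window_kb
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    if len(clumped) == 0:
        raise PipelineError(stage, "no instruments remain after clumping")

    stage = "qc"
    flagged = instruments.maf_check(clumped, config.maf_min)
    kept = clumped.subset([s for s in clumped.records if s not in set(flagged)])
    kept = instruments.apply_exclusion_list(kept, config.exclude_snps)
    if len(kept) == 0:
        raise PipelineError(stage, "no instruments remain after MAF/exclusion QC")
    strengths = instruments.instrument_strengths(kept, formula=config.r2_formula)
    strong_ids = instruments.weak_instrument_filter(strengths, config.f_min)
    kept = kept.subset(strong_ids)
    strengths = [s for s in strengths if s.snp_id in set(strong_ids)]
    if len(kept) == 0:
        raise PipelineError(stage, "no instruments remain after the weak-instrument filter")
    r2_sum = sum(s.r2 for s in strengths)

    bonf = power.bonferroni_threshold(config.alpha, config.n_tests)

    est_rows, diag_rows, loo_rows = [], [], []
    scatter_rows, line_rows, steiger_cols = [], [], {}
    primary_by_outcome: dict[str, estimators.MrEstimate] = {}
    seed_seq = np.random.SeedSequence(config.seed)
    outcome_seeds = {
        label: int(s.generate_state(1)[0] % 2**31)
        for label, s in zip(outcomes, seed_seq.spawn(len(outcomes)))
    }

    for label, outcome in outcomes.items():
        stage = f"harmonize[{label}]"
        try:
            harmonized = summary_io.harmonize(
                kept, outcome, palindrome_eaf_window=config.palindrome_eaf_window
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        if not harmonized:
            raise PipelineError(stage, "no instruments survived harmonization")

        stage = f"steiger[{label}]"
        n_out = outcome.n_default
        k_out = (
            outcome.n_cases_default / n_out
            if outcome.trait_type == "binary" and outcome.n_cases_default
            else None
        )
        try:
            steiger = instruments.steiger_filter(
                harmonized,
                n_exp=exposure.n_default,
                n_out=n_out,
                outcome_type=outcome.trait_type,
                case_fraction=k_out,
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        ok_ids = {s.snp_id for s in steiger if s.correct_direction}
        for s in steiger:
            if not s.correct_direction:
                log.warning("%s dropped by Steiger filtering for %s", s.snp_id, label)
        steiger_cols[label] = {s.snp_id: s.correct_direction for s in steiger}
        harmonized = [h for h in harmonized if h.snp_id in ok_ids]
        if len(harmonized) == 0:
            raise PipelineError(stage, "no instruments remain after Steiger filtering")

        stage = f"estimators[{label}]"
        try:
            battery = estimators.all_estimates(
                harmonized, n_boot=config.n_boot, seed=outcome_seeds[label]
            )
            ratios = estimators.wald_ratios(harmonized)
            het = heterogeneity.cochran_q(ratios)
            _, intercept = estimators.egger(harmonized)
            loo = estimators.leave_one_out(harmonized, method=config.primary_method)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        for est in battery:
            est_rows.append(
                {
                    "outcome": label,
                    "method": est.method,
                    "nsnp": est.n_snps,
                    "b": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "or": est.or_value,
                    "or_lci": est.or_ci_low,
                    "or_uci": est.or_ci_high,
                    "pval": est.pvalue,
                    "significant": est.pvalue < bonf,
                    "or_display": _fmt_or(est.or_value),
                    "ci_display": f"({_fmt_or(est.or_ci_low)}, {_fmt_or(est.or_ci_high)})",
                    "pval_display": _fmt_p(est.pvalue),
                }
            )
            if est.method == config.primary_method:
                primary_by_outcome[label] = est
        diag_rows.append(
            {
                "outcome": label,
                "q": het.q,
                "df": het.df,
                "q_pval": het.pvalue,
                "i2_pct": het.i2,
                "heterogeneous": heterogeneity.flag_mr_heterogeneity(het),
                "egger_intercept": intercept.intercept,
                "egger_intercept_se": intercept.se,
                "egger_intercept_pval": intercept.pvalue,
            }
        )
        for sid, est in loo:
            loo_rows.append(
                {
                    "outcome": label,
                    "excluded_snp": sid,
                    "method": est.method,
                    "b": est.beta,
                    "se": est.se,
                    "or": est.or_value,
                    "or_lci": est.or_ci_low,
                    "or_uci": est.or_ci_high,
                    "pval": est.pvalue,
                }
            )
        for h in harmonized:
            scatter_rows.append(
                {
                    "outcome": label,
                    "SNP": h.snp_id,
                    "beta_exp": h.beta_exp,
                    "se_exp": h.se_exp,
                    "beta_out": h.beta_out,
                    "se_out": h.se_out,
                }
            )
        for est in battery:
            line_rows.append(
                {
                    "outcome": label,
                    "method": est.method,
                    "slope": est.beta,
                    "intercept": intercept.intercept if est.method == "egger_slope" else 0.0,
                }
            )

    # --- cross-cohort meta-analysis -------------------------------------
    stage = "meta"
    try:
        labels = list(primary_by_outcome)
        meta = heterogeneity.meta_analyse(
            [primary_by_outcome[label] for label in labels], model="auto"
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    meta_rows = []
    for label, wpct in zip(labels, meta.weights_pct):
        est = primary_by_outcome[label]
        meta_rows.append(
            {
                "study": label,
                "b": est.beta,
                "se": est.se,
                "or": est.or_value,
                "or_lci": est.or_ci_low,
                "or_uci": est.or_ci_high,
                "weight_pct": wpct,
                "model": "",
                "q": "",
                "q_pval": "",
                "i2_pct": "",
                "tau2": "",
                "significant": "",
            }
        )
    meta_rows.append(
        {
            "study": "pooled",
            "b": meta.beta_pooled,
            "se": meta.se_pooled,
            "or": meta.or_pooled,
            "or_lci": meta.or_ci_low,
            "or_uci": meta.or_ci_high,
            "weight_pct": 100.0,
            "model": meta.model,
            "q": meta.het.q,
            "q_pval": meta.het.pvalue,
            "i2_pct": meta.het.i2,
            "tau2": meta.tau2,
            "significant": meta.pvalue < bonf,
        }
    )

    stage = "power"
    first_label = labels[0]
    first_outcome = outcomes[first_label]
    try:
        pw = power.binary_outcome_power(
            power.PowerParams(
                n=first_outcome.n_default,
                case_fraction=first_outcome.n_cases_default / first_outcome.n_default,
                or_hypo=primary_by_outcome[first_label].or_value,
                r2_sum=r2_sum,
                alpha=config.alpha,
            )
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    inst_rows = []
    for s in strengths:
        rec = kept[s.snp_id]
        row = {
            "SNP": s.snp_id,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "effect_allele": rec.effect_allele,
            "other_allele": rec.other_allele,
            "eaf": rec.eaf,
            "beta": rec.beta,
            "se": rec.se,
            "pval": rec.pvalue,
            "r2_pct": 100.0 * s.r2,
            "f_stat": s.f_stat,
        }
        for label in outcomes:
            row[f"steiger_ok_{label}"] = steiger_cols[label].get(s.snp_id, False)
        inst_rows.append(row)

    bundle: dict[str, Any] = {
        "instruments": pd.DataFrame(inst_rows),
        "estimates": pd.DataFrame(est_rows),
        "diagnostics": pd.DataFrame(diag_rows),
        "meta": pd.DataFrame(meta_rows),
        "scatter": pd.DataFrame(scatter_rows),
        "scatter_lines": pd.DataFrame(line_rows),
        "loo": pd.DataFrame(loo_rows),
        "power": pd.DataFrame(
            [
                {
                    "n": first_outcome.n_default,
                    "case_fraction": first_outcome.n_cases_default / first_outcome.n_default,
                    "or_hypo": primary_by_outcome[first_label].or_value,
                    "r2_sum": r2_sum,
                    "alpha": config.alpha,
                    "ncp": pw.ncp,
                    "power": pw.power,
                    "power_pct": 100.0 * pw.power,
                }
            ]
        ),
        "bonferroni": bonf,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: Mapping[str, Any], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    json_bundle: dict[str, Any] = {}
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
            json_bundle[name] = obj.to_dict(orient="records")
        else:
            json_bundle[name] = obj
    with open(out_dir / "results.json", "w") as fh:
        json.dump(json_bundle, fh, indent=2, sort_keys=True)
    log.info("wrote %d tables to %s", len(json_bundle), out_dir)
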