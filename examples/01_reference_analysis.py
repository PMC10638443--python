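"""Reproduce the uridine -> atrial fibrillation analysis end to end.

Runs the full pipeline on the embedded three-SNP instrument table (uridine
exposure GWAS, N = 7,824; three AF outcome GWAS) and prints the per-cohort
causal odds ratios, diagnostics and the pooled meta-analysis.
"""
import tsmr

bundle = tsmr.run_pipeline(tsmr.AnalysisConfig(seed=1))

print("Causal effect of plasma uridine (per SD) on atrial fibrillation:")
est = bundle["estimates"]
for _, row in est[est.method.isin(["ivw_fe", "ivw_mre"])].iterrows():
    print(f"  {row.outcome:8s} {row.method:8s} OR {row.or_display} "
          f"{row.ci_display}  p = {row.pval_display}")

print("\nHeterogeneity / pleiotropy diagnostics per outcome:")
for _, row in bundle["diagnostics"].iterrows():
    print(f"  {row.outcome:8s} Q p = {row.q_pval:.3f}  I2 = {row.i2_pct:.0f}%  "
          f"Egger intercept = {row.egger_intercept:.2f} (p = {row.egger_intercept_pval:.2f})")

pooled = bundle["meta"].iloc[-1]
print(f"\nMeta-analysis of the three cohorts ({pooled.model}-effects): "
      f"OR {pooled['or']:.2f} (95% CI {pooled.or_lci:.2f}, {pooled.or_uci:.2f})")
print(f"Bonferroni threshold for 3 outcome datasets: p < {bundle['bonferroni']:.3f}")
print(f"Power to detect the observed OR in the primary cohort: "
      f"{bundle['power'].loc[0, 'power_pct']:.0f}%")
# An OR below 1 means genetically higher uridine predicts *less* AF; the
# protective estimate is consistent across cohorts and their pooled analysis.
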