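# Methods

This note documents the statistical conventions `tsmr` implements, the
choices made where the literature admits more than one, and what the
synthetic-data generator does and does not emulate.

## Setting and assumptions

Two-sample summary-data Mendelian randomisation treats SNPs as instrumental
variables for a modifiable exposure. Validity rests on the three IV
assumptions: each instrument is associated with the exposure (relevance),
independent of confounders of the exposure–outcome relationship
(independence), and affects the outcome only through the exposure
(exclusion restriction). The package's QC operations map onto these:
the p < 5×10⁻⁸ filter, F-statistic screen and LD clumping address
relevance and instrument independence; exclusion lists (standing in for
confounder-lookup services) address independence; Steiger filtering and the
MR-Egger intercept probe the exclusion restriction. Exposure effects are in
SD units of a continuous trait; outcome effects are log-odds from a binary
GWAS, so pooled estimates exponentiate to odds ratios per SD of exposure.

## Harmonization

Records are matched by rsID only; positions are carried as metadata for
clumping windows. Outcome alleles are compared with the exposure's as
reported and, failing that, after strand complementation; a swapped match
negates the outcome beta and complements its frequency. Palindromic (A/T,
C/G) variants are unresolvable by strand complementation, so they are
dropped when the exposure MAF is within 0.08 of 0.5 (configurable); outside
that window the reported orientation is trusted but the record stays
flagged. Finally every instrument is oriented so β_exp > 0 (negating both
betas and complementing the frequency as needed) — the orientation required
by regression-based estimators such as MR-Egger, and harmless to the
ratio-based ones. Indels and multi-allelic records are rejected at parse
time. All estimators are equivariant under re-orienting the reported allele
of any input record; this is property-tested.

## Instrument strength

Variance explained uses, by default, the formula

R² = 2·EAF(1−EAF)·β² / (2·EAF(1−EAF)·β² + 2·EAF(1−EAF)·se·N·β²),

which algebraically reduces to 1/(1 + se·N): EAF and β cancel. This is not
the conventional expression (which carries se²·N, i.e. β²/(β² + N·se²)),
but it is the one under which the embedded reference table's per-SNP R²
values (6.993%, 6.993%, 6.303%, summing to 20.3%) are internally
consistent, and the acceptance surface of the reference analysis depends on
it. The conventional formula is available via `formula="standard"`. The
F-statistic is F = R²(N−k−1)/(1−R²) with k the number of instruments;
instruments with F < 10 are removed. On the reference table this yields
F ≈ 588/588/526 — the table's own printed F column (≈38/38/31) is not
derivable from these R² and N values under this formula, so F values are
reported but never asserted against published numbers.

## Estimators

- **Wald ratio**: θ̂_j = β_out/β_exp with first-order SE se_out/|β_exp|.
  The exposure-uncertainty (second-order) term is deliberately omitted:
  with strong instruments it is negligible, and the first-order convention
  is what reproduces the reference confidence intervals. Its cost is that
  under a nonzero causal effect the ratios are mildly over-dispersed
  relative to their nominal SEs; the multiplicative random-effects model
  absorbs exactly this.
- **IVW**: inverse-variance weighted mean of the ratios. Fixed-effects
  SE = (Σw)^(−1/2); multiplicative random effects scales it by √(Q/(n−1))
  with *no* floor at 1, so under-dispersion (Q < n−1) shrinks the interval.
  The no-floor convention is required for internal consistency with the
  reference analysis and is reported as such. With n = 2 the scale estimate
  has one degree of freedom and a warning is emitted. A single-ratio fixed
  IVW is exactly that Wald ratio.
- **MR-Egger**: weighted least squares of β_out on β_exp with intercept,
  weights se_out^(−2), inference on t(n−2) with the residual variance
  scaling the SEs (again no floor, mirroring the IVW convention). The
  intercept estimates the average directional pleiotropic effect; p < 0.05
  is the conventional alarm. At least 3 instruments are required, and the
  fit is refused when all β_exp coincide (slope and intercept not
  separately identified).
- **Weighted/simple median**: the interpolated weighted median — sort
  ratios, normalise weights, linearly interpolate the 0.5 crossing of the
  cumulative weights minus half each weight. This interpolation convention
  is fixed because alternatives shift the estimate by a percent or two at
  n = 3. SEs come from a seeded parametric bootstrap (each ratio resampled
  from Normal(θ̂_j, σ_j), weights held fixed; default 1,000 replicates);
  p-values are two-sided normal.
- **Simple mode**: the maximiser of a normal-kernel density over the
  unweighted ratios, bandwidth h = 0.9·min(sd, 1.4826·MAD)·n^(−1/5)
  (falling back to the sd when the MAD is zero, as in a two-and-one ratio
  split), times a user `bandwidth_factor`. There is no community-standard
  bandwidth for this estimator; ours is a Silverman-type rule on a robust
  scale and is documented rather than tuned. Bootstrap SEs re-derive the
  bandwidth per replicate.
- **Leave-one-out**: the primary estimator re-run excluding each instrument
  in turn; with one instrument left, fixed-effects pooling (≡ the remaining
  Wald ratio) is used.

95% intervals use the exact normal 97.5% quantile (1.959964…) on the log
scale throughout; displayed odds ratios round to 2 decimals and p-values to
3 significant figures, with full precision retained in TSV/JSON output.

## Heterogeneity and meta-analysis

Cochran's Q among Wald ratios is computed around the fixed-effects IVW
estimate with df = n−1 and an upper-tail chi-square p;
I² = max(0, (Q−df)/Q)·100. Two distinct decision rules are module
constants: heterogeneity among instruments is flagged at Q p < 0.05 or
I² > 25%, while the cross-cohort meta-analysis switches to random effects
at Q p < 0.1 or I² > 50%. The meta-analysis pools the per-cohort
multiplicative random-effects IVW estimates; the random-effects variant
uses DerSimonian–Laird τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). Meta p-values
are two-sided normal without a Knapp–Hartung adjustment.

## Steiger directionality

The SNP–trait correlation in each sample is recovered from the summary
test statistic, r² = t²/(t² + n − 2) with t = β/se. For a binary outcome
the observed-scale r² is mapped to the liability scale by the factor
K(1−K)/φ(Φ⁻¹(K))², with K the case fraction, so exposure and outcome
correlations are compared on a common continuous-trait scale. The direction
is "correct" when the instrument explains more variance in the exposure
than the outcome; the p-value is a two-sided Fisher z-test on the
difference of the two independent-sample correlations (so swapping roles
negates the direction and preserves p). Only the boolean direction feeds
the pipeline's filtering; the liability approximation is coarse and the
p-value should be read qualitatively.

## Power

Binary-outcome power follows the mRnd formulation: the hypothesized OR is
attenuated to b = K(OR/(1+K(OR−1))−1); the estimator variance is
v = (K(1−K)−b²)/(N·R²); power is the mass of a non-central chi-square(1,
NCP = b²/v) beyond the central (1−α) quantile. The chi-square rather than
normal-quantile formulation is used; at the NCPs of interest the two agree
to display precision. R² entering the pipeline's power step is the summed
per-instrument variance explained.

## Synthetic data

`simulate_two_sample` draws, per SNP: allele frequency p ~ Uniform(0.1,
0.9); true exposure effect γ ~ Normal(0.4, 0.1) with |γ| clipped at ≥ 0.2;
a direct (pleiotropic) outcome effect α, zero with probability
1 − `invalid_fraction`, else Normal(pleiotropy mean, sd) — independent of γ,
so InSIDE holds by construction. Observed effects are
β_x ~ N(γ, se_x), se_x = (2p(1−p)N_x)^(−1/2), and
β_y ~ N(β*γ + α, se_y), se_y = (2p(1−p)N_y K(1−K))^(−1/2) — the score-test
SEs for a standardised continuous exposure and a binary (logistic) outcome.
Defaults mirror the reference design: N_x = 7,824, N_y = 1,030,836,
K = 60,620/1,030,836, β* = −1.3 (the headline log-OR), and instruments of
the strength metabolite GWAS actually deliver (each ≈ 3–8% of exposure
variance, like the ≈7% per-SNP R² of the embedded table). A single integer
seed makes output bit-identical.

What the generator does *not* emulate: LD between instruments (the clumping
generator builds block-diagonal r² matrices separately), sample overlap
between the two GWAS, winner's-curse selection of instruments, allele
miscoding/strand errors, covariate adjustment, or case–control ascertainment
beyond the K(1−K) variance scaling. Calibration results on these
simulations therefore validate the estimators' arithmetic and sampling
theory, not their robustness to those real-data complications.

Simulation-based checks in the test suite use 500 replicates of 50–100
instruments for type-I error, bias and coverage, and 100–200 replicates for
secondary properties — sizes at which binomial/Monte-Carlo noise is well
inside the asserted bands while the whole suite stays quick.

## Degenerate inputs and numerical conventions

Empty intersections, zero exposure betas, non-positive SEs, malformed LD
matrices and invalid thresholds raise typed exceptions
(`ValidationError`, `ConfigurationError`, `NoSharedInstrumentsError`);
pipeline stages wrap failures in a `PipelineError` naming the stage, and
partial outputs are never written. p-values are clamped to (0, 1] (an
exactly-zero tail probability becomes the smallest positive float).
Identical ratios give Q = 0, I² = 0, p = 1; a point-mass of ratios makes
the mode estimator return that value directly. Harmonized-instrument files
write floats via shortest round-trip representation and are parsed with
round-trip precision, so write→read is lossless. Clumping ties on p-value
are broken by input order (stable sort).

## Known limitations

- The Wald-ratio SE ignores exposure uncertainty by design; with weak
  instruments (F near 10) both bias and coverage degrade.
- MR-Egger with 3 instruments has one residual degree of freedom; its slope
  CI is wide and its intercept test underpowered — it is a qualitative
  diagnostic at that size.
- The Steiger liability-scale conversion is an approximation; near-ties in
  explained variance should not be over-interpreted.
- No support for correlated instruments in estimation (clumping is assumed
  to have removed LD), proxy-SNP lookup, multivariable or nonlinear MR, or
  outlier-removal methods that need larger instrument counts.
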