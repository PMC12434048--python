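# Methods

## Why variance heterogeneity signals interaction

Consider a trait generated by `Y = β₁G₁ + β₂G₂ + β_INT·G₁G₂ + ε` with
independent biallelic loci `G₁, G₂ ∈ {0,1,2}`.  Conditional on `G₁ = g`,

    Var(Y | G₁ = g) = (β₂ + β_INT·g)² · Var(G₂) + Var(ε),

so a non-zero interaction makes the conditional variance a function of the
allele count at `G₁` even though no marginal effect of `G₂` or the
interaction is modelled.  The same algebra applies verbatim when `G₂` is a
three-level environmental exposure, which is why a vQTL screen is a cheap
pre-filter for both GxG and GxE.  All tests in this package target the
null "phenotypic variance is constant across the genotype groups of the
tested SNP".

## Pre-adjustment

Every test consumes residuals of `Y` on an intercept, two genotype
indicator variables and the covariates.  Using indicators (rather than the
allele count) removes dominance as well as additive mean effects; a large
unremoved main effect is a known source of spurious vQTL signal.  Missing
data are removed listwise before fitting — the simplest contract, and the
one the per-variant NA accounting in the scan driver is built around.
Samples dropped for one variant do not affect another variant's analysis.

Dispersion is measured as `D = |e − median(e | group)|`.  The group
*median* (not mean) gives robustness to outliers; the *absolute* value is
essential — the group-median subtraction annihilates location information,
and rank or regression tests on signed deviations would test location, not
spread.  The sample median is the usual midpoint-of-central-order-statistics
definition.  Genotypes must be hard calls: group medians are undefined for
fractional dosages, so dosage input is rejected at the type level rather
than silently rounded.

## The five tests

**KW** ranks all `D` jointly (average ranks on ties) and compares group
mean ranks; the statistic `(N−1)·Σnᵢ(r̄ᵢ−r̄)²/Σ(r−r̄)²` is χ²(M−1).  The
denominator is computed from the realized ranks, which makes the usual tie
correction implicit.

**BF** is the one-way ANOVA F of `D` on genotype categories, F(M−1, N−M).
It is algebraically identical to regressing `D` on the two genotype
indicators, which is how the oracle test verifies it.

**DRM** regresses `D` on the allele count (a 2-parameter OLS) and reports
the two-sided t test of the slope on N−2 df.  Treating genotype as
continuous costs one degree of freedom less and, more importantly, avoids
BF's sensitivity to a sparse minor-homozygote group at low MAF.

**DGLM** models the residuals as heteroscedastic normal with
`log σ² = γ₀ + γ₁·count`, alternating weighted least squares for the mean
with a gamma GLM (log link, prior weight ½) on squared residuals for the
dispersion.  Because the IRLS weight of a log-link gamma model with
constant prior weight is constant, each dispersion scoring step reduces to
an OLS solve on the working response.  Convergence is declared when the
relative change in the heteroscedastic-normal deviance
`Σ(log σ² + r²/σ²)` drops below 1e-8 (cap 50 outer iterations; a
non-converged fit is flagged and the last iterate reported).  Squared
residuals are floored at `1e-10·Var(e)` so the log link never sees zero.
Significance is a Wald z on γ₁ with covariance `2(ZᵀZ)⁻¹`: the squared
residual of a normal variate is `σ²χ²₁`, a gamma variate whose variance
fixes the GLM scale at 1 given prior weight ½.  A Wald test was chosen
over an LRT to match the reporting convention of standard double-GLM
software; the empirical size at N = 2,000 is 0.049 over 8,000 null
replicates.  `DGLM_INT` first maps residuals through the rank-based
inverse-normal transform `Φ⁻¹((r − 3/8)/(N + 1/4))` (Blom offset, the GWAS
convention), which restores calibration under heavy tails but — as the
benchmark shows — not under skew, since ranks cannot remove the
mean–variance coupling a skewed error law induces in the groups.

**QUAIL** estimates the quantile-integrated effect
`β_QI = ∫₀^0.5 (β_{1−τ} − β_τ)dτ`, the accumulated upper-minus-lower
quantile slope difference, positive when higher allele counts widen the
distribution.  The integral is discretized by the midpoint rule on K equal
bins of (0, 0.5), `τ_k = (2k−1)/(4K)`, each rectangle of width `1/(2K)`.
Fitting 2K quantile regressions per variant is far too slow for a scan, so
inference uses the integrated rank-score construction: each sample gets
the score `η = (1/K)Σ_k[ψ_{1−τk}(e) − ψ_{τk}(e)]` with
`ψ_τ(e) = τ − 1{e ≤ Q̂_τ}` and `Q̂_τ` the marginal sample quantile, and the
OLS slope of `η` on allele count is t-tested.  The expensive
quantile-regression path is retained behind `compute_effect=True` for the
point estimate on follow-up variants; K defaults to 100.  Covariates are
handled entirely by the pre-residualization and are not re-fit per
quantile.  Known limitation: nothing guards against quantile crossing in
the per-quantile estimates, which can blunt the point estimate when K is
large relative to N (a warning fires for N < 10K).

All reported p-values are two-sided and floored at the smallest positive
double to keep downstream `log10` finite.

## Simulator and benchmark harness

Genotypes are i.i.d. `Binomial(2, MAF)` (Hardy–Weinberg); traits follow
the two-locus model above with the error drawn from a standard normal,
t(3 df) or χ²(6 df) law and then **z-scored with the replicate's own
sample mean and SD (ddof = 1)**, so the stochastic part has exactly unit
variance in every replicate and the variance explained by the genetic
terms is comparable across error laws.  The t(3) law mimics heavy-tailed
traits, χ²(6) the right skew typical of biomarkers such as lipids.  What
the simulator deliberately does not emulate: linkage disequilibrium
between the two loci, covariate structure beyond optional noise columns,
relatedness, and genotyping error — so passing benchmarks demonstrate
statistical calibration of the tests, not robustness to those data
pathologies.

FPR is the fraction of null replicates (`β_INT = 0`) with `p < α`; power
the same fraction under `β_INT ≠ 0`.  Replicate seeds are spawned from the
scenario seed via `SeedSequence`, making every estimate bit-reproducible
and independent of any batching.  Failures inside a replicate (e.g. a
monomorphic draw at extreme MAF) are counted and reported, never silently
dropped.  Desk-scale defaults — N in the low thousands, 1,000–2,000
replicates, α = 0.05 for calibration and 1e-3 for power — are the
package's own choice of problem size for a single-CPU workflow; the
scenario object accepts biobank-scale settings (N ≈ 1.5e5, 2e4 replicates,
α = 5e-8) unchanged.  Two desk-scale findings deserve a note: BF's
kurtotic-trait inflation is a *tail* phenomenon — its size at α = 0.05 is
nominal while its rejection rate at α = 1e-3 is ~6× nominal — and the
power gaps between the near-tied parametric tests (DGLM vs DRM under
normal errors) are within Monte Carlo noise at these sizes, so ordering
claims are asserted as paired non-inferiority rather than strict
inequalities.

QQ summaries pair sorted observed −log₁₀ p against `−log₁₀(k/(n+1))` and
report the observed/expected ratio at the median point, a genomic-control
style slope.

## Scan driver and fixtures

The scan recomputes MAF and minor-allele orientation per variant on the
analyzed samples (flipping to `2 − calls` when the counted allele exceeds
frequency 0.5; exact ties keep file orientation), filters at MAF ≥ 0.05 by
default (rarer interaction hits replicate poorly), and emits exactly one
row per input variant — failures become NA rows with a reason code.  PLINK
`.bim` positions are passed through untouched.  The PLINK1 variant-major
`.bed` codec is implemented in `vqtlkit.io` (two bits per sample, A1
counted, `01` missing).

The fixture generator builds fully synthetic cohorts: Hardy–Weinberg
genotypes at uniform MAFs, sex and age covariates with fixed effects
(0.25 and 0.02/year), planted mean effects, and normal noise whose
log-variance is linear in the planted variants' allele counts — the exact
generative model the DGLM assumes, which is what makes planted-slope
recovery a sharp test.  A ground-truth manifest is written alongside.

## Follow-up analyses

Clumping is greedy on marginal r² only: visit hits by ascending p (ties
broken lexicographically by id), keep a variant iff `p < 5e-8` and r² with
every kept lead is below 0.01.  No base-pair window or secondary threshold
is applied — vQTL hit lists are short.

Direct GxE/GxG regress the **raw trait** (not the residual) on the allele
count(s), all exposure main effects, optional ancestry PCs, and a single
product term per fit, preserving the main-effects-below-interaction
hierarchy.  The product of two allele counts takes values {0, 1, 2, 4}.
Outputs carry raw two-sided p-values (no internal multiplicity
correction; users apply Bonferroni over the 210/435 tests as appropriate)
plus a signed `−log₁₀ p` whose sign is `sign(β̂_int·β̂_g)` — positive when
the partner pushes the genetic effect further from zero (exacerbation),
negative when it attenuates; the same-model genetic main effect is used
for the sign, and the convention extends naturally to negative main
effects.  Exposure columns collinear with the intercept or each other are
dropped up front with a warning, since they would poison every design in
the scan.

## Known limitations

* Hard calls only — no dosage/BGEN support, and no VCF input.
* No mixed-model or kinship adjustment; relatedness must be pruned
  upstream.
* Rare variants (MAF < 0.05) are filtered, not specially handled.
* The integrated rank-score QUAIL p-value is asymptotic; at N below a few
  hundred its calibration degrades before the other tests' does.
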