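# Methods

## Design

medmr implements the two-sample summary-statistics Mendelian-randomization
(MR) mediation design: genetic variants instrument a microbiome exposure X,
a circulating metabolite M, and a disease outcome Y, and the causal chain
X → M → Y is decomposed into a mediated and a direct component. The usual IV
assumptions apply per link (relevance, independence from confounders,
exclusion restriction), and the chain-level decomposition additionally
assumes the two legs combine linearly on their analysis scales (log-OR for
binary outcomes). All estimation uses instrument-level data only: per-SNP
effect sizes, standard errors and p-values from three (possibly
non-overlapping) GWAS.

## Harmonization

Outcome records are oriented to the exposure's effect allele. Exact label
matches are kept; swapped labels flip the sign of the outcome beta (and
mirror its allele frequency); strand-complement labels are resolved through
the complement map; anything else is dropped as incompatible. Palindromic
variants (A/T, C/G) are inherently strand-ambiguous, so they are kept only
when both sides carry an allele frequency, the label-aligned frequencies
fall on the same side of 0.5, and both minor-allele frequencies are below
`palindrome_eaf_limit` (default 0.42, the common two-sample-MR convention);
otherwise they are dropped. With a missing frequency on either side the
variant is always dropped — conservative and deterministic. These rules make
harmonization idempotent and invariant to relabeling the outcome's alleles.

## Instrument selection

Three filters compose, in order: association (*P* < `p_max`, default 1e−5),
greedy LD clumping, and per-SNP strength (F > `f_min`, default 10).
Clumping sorts candidates by ascending p-value with fully deterministic tie
breaking (chromosome, position, variant id), keeps the best remaining
variant and removes every other candidate with r² ≥ `clump_r2` (default
0.001) within `window_kb` (default 10,000 kb) on the same chromosome.
Cross-chromosome LD is taken as zero; a candidate missing from the LD matrix
while sharing a chromosome with another candidate is an error rather than a
silent zero.

Per-SNP strength uses summary-data surrogates only. With an effect-allele
frequency f, variance explained is R² = 2f(1−f)β² under a unit-variance
(SD-scale) trait — the convention of metabolite GWAS; without one,
R² = F/(F+n−2) with F = (β/se)², and in both cases
F = R²(n−2)/(1−R²). Both forms are exposed; which one applied is visible
from the record's fields.

A caveat worth knowing: "tightening a threshold can only shrink the
selection" is guaranteed for the F filter, and for the p and r² thresholds
on block-structured LD (uniform within-block correlation, independent
blocks). On adversarial LD graphs greedy clumping can return a *larger* set
after tightening, because removing a hub candidate frees all of its
neighbors. Block LD is what real panels approximate and what the synthetic
generator emits, so the property is validated in that regime.

## Estimators

With harmonized pairs (bˣ_j, bʸ_j) and weights w_j = 1/se_ʸ_j²:

- **Wald ratio** (single instrument): bʸ/bˣ with first-order SE
  se_ʸ/|bˣ|, accurate when se_ˣ/|bˣ| is small; the second-order
  delta-method SE is used as a test oracle, not in production output.
- **IVW**: the zero-intercept weighted regression
  β̂ = Σw bˣbʸ / Σw (bˣ)². The default SE is multiplicative random
  effects with the scale floored at one, se = (Σw (bˣ)²)^{−1/2} ·
  max(1, √(Q/(k−1))) — identical to fixed effects whenever Q ≤ df, robust
  to mild heterogeneity otherwise. IVW p-values use the normal
  distribution. Both choices mirror the de-facto standard two-sample-MR
  software defaults.
- **MR-Egger**: weighted regression with a free intercept after flipping
  each instrument so bˣ ≥ 0 (the InSIDE orientation, which makes the
  intercept the average directional pleiotropy). Slope and intercept are
  tested with *plain* weighted-least-squares t statistics on k−2 df, i.e.
  the residual scale is estimated and **not** floored at one. This is a
  deliberate deviation from the software that floors it: with the scale
  estimated the intercept test is exactly t-distributed under the null
  (the package's simulations reproduce the nominal 5% level), whereas the
  floored variant is conservative.
- **Cochran's Q**: Σw (bʸ − fitted)² with k−1 df around the IVW line and
  k−2 around the Egger line, chi-square upper-tail p.
- Odds ratios and 95% CIs use the fixed multiplier 1.959964 throughout.

`MRModel(pairs).fit()` computes every applicable estimator (Wald for one
instrument, IVW for ≥ 2, Egger for ≥ 3) plus the sensitivity report and
returns an `MRResults` with `summary()` and a scatter `plot()`.

## Screening funnel

A forward result passes when IVW *P* < 0.05 **and** no diagnostic rejects:
Egger-intercept *P* > 0.05 and Q *P* > 0.05. A diagnostic that cannot be
computed (fewer than three instruments) cannot reject and therefore does not
veto — the funnel never silently discards an exposure for having few
instruments; it records the skip reason instead. Reverse MR then re-runs the
analysis with the disease as exposure and each passing microbe as outcome;
reverse *P* < 0.05 marks the pair bidirectional and removes it from
mediation, following the principle that mediation should only be attempted
for exposures without evidence of reverse causation. When the disease trait
yields no instruments reaching the microbe's panel, the reverse test is
recorded as absent and does not veto.

## Mediation decomposition

One nomenclature note: some two-step-MR write-ups label β₁·β₂ "β_direct" in
their formulas while reporting β₁·β₂ as the *mediated* effect wherever they
interpret results. medmr uses the standard product-of-coefficients
convention, which keeps formulas and reports self-consistent:

    mediated = β₁·β₂          direct = β_total − mediated
    proportion = mediated / β_total

The identity direct + mediated = β_total holds exactly (to one floating
rounding); the proportion may be negative when the mediated and total
effects oppose, and is never truncated. β_total is estimated on the full
microbe instrument set (not re-estimated after step-2 exclusion). "SNPs
correlated with step 1" is operationalized as: a mediator instrument is
excluded when it shares a variant id with a step-1 instrument or lies within
the clump window of one with r² ≥ `clump_r2` — the only reading computable
from summary data. Pairs absent from the LD matrix are treated as unlinked
in this specific exclusion (the two instrument panels may come from
different sources).

The mediated-effect SE is first-order delta (Sobel),
√(β₁²se₂² + β₂²se₁²), with a normal p-value; the proportion CI treats the
product and the total as independent (they share the microbe's instruments,
so this is an approximation; it is flagged unreliable whenever
|β_total| < 10·se_total). A percentile bootstrap over independent normal
draws of (β₁, β₂, β_total) (default 10,000 replicates, explicit seed) is
available as `ci_method="bootstrap"`; the significance flag always comes
from the deterministic Sobel test. Simulations at the package's default
chain (below) put the delta CI's coverage of the mediated effect at ~95%
and the mean estimated proportion within half a point of the true 14.4%.

## Multiplicity

Bonferroni thresholds are α_fw/m with explicit families — in the motivating
scan, 871 identified metabolites (α ≈ 5.74e−5), 207 shotgun-metagenomic taxa
(α ≈ 2.42e−4) and 196 16S taxa (α ≈ 2.55e−4). BH-FDR is the plain step-up
q_(i) = min_{j≥i} m·p_(j)/j capped at one, with no tie special-casing.
Family scoping is always the caller's decision (a runtime parameter), since
whether FDR should run per outcome, per rank or globally is a design choice,
not a computation.

## Paired pre/post arm

Statistics are computed on the abundances as given; the only transform is
explicit (`transform="log"`, requiring positive values) — nothing is ever
log-transformed implicitly. Per feature: two-sided paired *t* on
d = post − pre (n−1 SD), Cohen's d_z = mean(d)/sd(d), fold change on group
means mean(post)/mean(pre) with log₂ (a per-subject-ratio variant exists
behind a flag; group means are robust to zero post-values), BH-FDR scoped to
the caller's feature panel, and for features with *P* < 0.05 a seeded
percentile bootstrap CI for d_z (default 2,000 subject resamples; degenerate
replicates are skipped and counted, > 10% flags the CI) plus leave-one-out
ranges of *p* and d_z over exactly n refits. The bootstrap resamples the
*sorted* differences so results are invariant to subject ordering without
changing the resampling distribution; per-feature bootstrap seeds derive
from a CRC of the feature id, so panel composition does not shift them.

The seizure control rate is (pre − post)/pre × 100 (negative = worsening,
capped at 100 only by post ≥ 0). Spearman correlation of feature changes
with control rates uses average ranks; its two-sided p-value is an exact
enumeration over all n! permutations for n ≤ 7, a seeded Monte-Carlo
permutation test (100,000 draws) for 8 ≤ n ≤ 12, and the t approximation
above — a nine-subject cohort sits exactly where the asymptotic
approximation is poor. These correlations are never multiplicity-adjusted
and carry an explicit `exploratory` flag.

## Synthetic data

`simulate_chain` draws Binomial(2, maf) genotypes with Gaussian-copula LD:
within a block, each gamete's latent normals share correlation
`within_block_r` (the realized genotype r² is the thresholded, attenuated
version of it); blocks are independent and placed 15 Mb apart so the
10,000-kb clump window spans a block but not its neighbors. Phenotypes are

    X = Σ aⱼGⱼ (+ reverse_beta · L) + ε      (exposure)
    M = β₁X + Σ cⱼGⱼ + ε                      (mediator)
    Y = β_direct·X + β₂M + L + Σ dⱼGⱼ + ε    (outcome), L = Σ eⱼGⱼ

with disjoint causal-block groups for a (exposure), c (mediator) and e
(disease-specific loci, total heritability `outcome_h2`), optional per-SNP
pleiotropy dⱼ ~ N(0, `pleiotropy_sd`) (with an InSIDE-violating option that
couples dⱼ to instrument strength), and noise variances set so each trait
has approximately unit variance. Binary outcomes are generated through a
logistic link with the intercept solved for the target prevalence, and their
summary statistics come from per-SNP logistic fits (vectorized IRLS), so
mediation on the log-OR scale is exercised as with biobank endpoints. Each
trait's summary statistics are computed in its own independently drawn
cohort — the non-overlapping two-sample setting. The empirical genotype
correlation matrix of the exposure cohort is returned as the LD input, and
the truth record carries β₁, β₂, the direct effect, the implied total
β_direct + β₁β₂ and proportion mediated.

Defaults mirror the motivating study's regime scaled to desk size: n =
20,000 per cohort, 150 SNPs in 30 blocks (12 exposure, 12 mediator, 6
disease), within-block latent r = 0.3, maf ∈ (0.1, 0.4), exposure/mediator
heritabilities 0.25 (per-instrument F ≈ 100 at default n, comfortably past
the F > 10 filter), disease heritability 0.2, and planted effects β₁ = 0.3,
β₂ = 0.19, direct = 0.34 — chosen so the true mediated effect (0.057) and
proportion (14.4%) match the magnitude of the motivating study's headline
mediation row, making recovery checks directly interpretable.

The disease-specific loci matter for the reverse screen: they are the valid
reverse instruments, exactly as a disease GWAS's own hits are in practice.
In the realistic regime the microbe's effect on disease is far too small to
reach *P* < 1e−5 in the disease GWAS, so reverse instruments stay clean;
simulation configurations in the tests keep the forward effect in that
regime when the reverse filter itself is under study. Strong feedback
instead contaminates the microbe's instrument set and is caught earlier, by
the heterogeneity and pleiotropy diagnostics.

`simulate_paired_metabolome` plants per-feature effects on the log scale —
log(post/pre) ~ N(dz·σ, σ) with σ = `feature_noise_sd` — so the planted d_z
is exact on log abundances and attenuated on the raw scale (which is why the
generator-truth tests analyze with the explicit log transform). The default
panel is seven features with graded effects (d_z 2.0 … 0.5), echoing a
seven-member lipid panel with one dominant hit, among 200 features for nine
subjects. The seizure response is a strictly monotone bounded transform
(100·tanh(u/2)) of a latent variable with correlation `response_coupling`
(default 0.8) to the top feature's log change, so coupling 1 yields rank
correlation exactly 1.

What the generators deliberately do **not** emulate: compositionality and
zero-inflation of real microbiome relative abundances, population structure
and relatedness, sample overlap between GWAS, assay batch effects or
missingness in the metabolome, and integer seizure counts (frequencies are
continuous rates). Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated generative model, not robustness to
those real-data complications.

## Problem sizes and determinism

The validation suite uses: 500 null chains (n = 4,000, 45 SNPs) for screen
calibration; 200 chains at the default size for mediation recovery and CI
coverage; 100 random 50-instrument instances against a generic WLS oracle;
200 random LD configurations (≤ 12 SNPs) against a brute-force clumping
oracle; 1,000 random p-vectors against the literal BH step-up; 5,000 null
paired-t replicates and 500 bootstrap-coverage simulations at n = 50. The
acceptance script runs reduced replicate counts of the same experiments
(150/60/300) to stay around a minute of CPU. Every stochastic step takes an
explicit seed; identical configs reproduce byte-identical result tables
(the run manifest carries wall-clock timestamps and is excluded from the
byte-identity guarantee).

## Known limitations

- Two-step mediation assumes no exposure–mediator interaction and linearity
  on the analysis scale; log-OR-scale decomposition for binary outcomes is
  approximate (non-collapsibility is ignored, as is conventional).
- The proportion-mediated CI ignores the correlation between the product
  and the total induced by shared instruments.
- Weighted-median/mode estimators, MR-PRESSO, Steiger filtering and
  multivariable MR are out of scope.
- The Wald-ratio SE is first-order; with weak instruments
  (se_ˣ/|bˣ| ≳ 0.1) it understates uncertainty.
- LD is taken as given (file or simulator); the package never estimates LD
  from genotype panels.
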