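# Methods

This note records the statistical model behind `gbascan`, the choices
made where the design was genuinely open, what the synthetic cohorts do
and do not emulate, and the numerical conventions.

## Matched-pair conditional logistic regression

For a 1:1 matched design the conditional likelihood of pair *i* given
that exactly one member is a case is

L_i(β) = expit( (x_case,i − x_control,i)ᵀ β ),

so the per-pair nuisance intercepts cancel and the whole scan reduces to
an intercept-free logistic regression on pair-difference rows with an
all-ones response. The solver is a damped Newton iteration (step norm
capped at 4, |log-OR| above 15 treated as separation) vectorised over
permutation replicates: swapping case/control within pair *i* multiplies
row *i* by −1, so one (SNP, model) permutation pass is a single batched
fit over the ±1 sign matrix. Covariates (BMI) travel with the
individual and their difference column flips sign with the pair.

Genotype codings: *trend* = minor-allele count (1-df Wald); *nominal* =
indicators for heterozygote and minor homozygote against the major
homozygote (2-df Wald). When a genotype class yields an all-zero
difference column, the indicator is dropped and the recorded df falls to
1. Pairs with a missing genotype in either member are dropped for that
SNP only; the conditional likelihood needs complete pairs and we do not
impute. Non-converged or non-estimable fits are excluded from the gene
combination in observed *and* permuted data alike, which preserves the
permutation null.

## The gene statistic and its null

The truncated product W multiplies the SNP p-values at or below
τ = 0.05 (the boundary is included; W = 1 when nothing qualifies). Under
L independent uniforms,

P(W ≤ w) = Σ_{k=1..L} C(L,k)(1−τ)^{L−k} ×
           { τ^k                                    if w > τ^k
           { w Σ_{s<k} (k ln τ − ln w)^s / s!       otherwise,

evaluated in log space (binomial weights via log-gamma, inner sums via
log-sum-exp), so L in the thousands and W below 10⁻³⁰⁰ are exact to
double precision. An equivalent gamma-tail mixture representation —
conditional on k entries below τ the product is τ^k e^(−G), G ∼
Gamma(k, 1) — serves as an independent oracle in the tests.

Because L is fixed within a gene, ranking permutation replicates by W is
identical to ranking by analytic p; the permutation comparison therefore
uses log W with tie-inclusive ≤, and the empirical p-value is
(1 + #{W_perm ≤ W_obs}) / (B + 1). Replicates draw independent within-
pair swaps with probability 1/2; an exhaustive 2ⁿ enumeration mode
exists for cohorts of ≤ 20 pairs and is used to test exactness.

**Discreteness caveat.** W has an atom at 1 with null mass ≈ (1−τ)^L
(LD increases it), so the gene-level empirical p has a matching atom and
is only *sub*-uniform for SNP-poor genes. Calibration is therefore
demonstrated two ways: validity (P(p ≤ x) ≤ x) on small genes, and full
KS uniformity on a SNP-rich, LD-free calibration cohort (60 SNPs/gene,
atom ≈ 0.05). The same discreteness argument applies to single-SNP Wald
p-values, whose score sum can be exactly zero; their calibration is
checked as rejection-rate bands rather than a literal KS test.

## Two-step selection

Step 1 ("prioritization"): per model, BH-FDR across all genes' analytic
p; a gene is prioritized when any model's FDR < 10⁻³. The stringent
level compensates for the analytic null's independence assumption, which
LD violates. Step 2 ("permutation validation"): the empirical p-values
of prioritized genes are pooled across the four models into a single
BH-FDR and a gene is identified when any pooled entry is < 5×10⁻². The
4-bit significance pattern records which models met step 1 (model order
CLR_N, CLR_C, CLR_N,BMI, CLR_C,BMI).

## QC and stratification conventions

Filter order: sample call rate ≥ 0.99 → SNP call rate ≥ 0.9 → exact HWE
(BH-FDR over all surviving SNPs, pooled cases + controls; removed below
10⁻³) → MAF ≥ 0.01 recomputed after sample removal. The HWE exact test
is the standard conditional-on-allele-counts sum of no-more-probable
heterozygote tables, ties included, no mid-p. λ is the median of the
1-df trend statistics over the χ²(1) median (0.45494), computed from
CLR_C by convention. Genotype PCA centres each SNP at twice its allele
frequency and scales by √(p(1−p)), missing imputed to the column mean;
the median test is Mood's with a continuity-free chi-square and a Fisher
fallback when an expected cell is below 5.

## Downstream operators

Risky/protective labels compare per-genotype-class frequencies between
groups. A subject's risk score per gene is the proportion of their
non-missing, non-neutrally-labelled genotypes carrying the target label
— neutral classes enter neither numerator nor denominator — averaged
over the identified genes; top-k selection breaks ties by sample id so
the result is order-invariant. Quantile normalization replaces each
column's order statistics by the cross-column mean with average-rank tie
handling and is idempotent. Differential expression is the linear model
value ~ group (+ BMI), i.e. one-way ANOVA or BMI-adjusted ANCOVA, with
the group-coefficient t-test; a constant covariate is dropped with a
warning, making ANCOVA degenerate to ANOVA exactly. Clustering uses
d = (1 − Kendall τ_b)/2 (the name fixes only the correlation, not the
map; this choice lands agreement on [0,1]) with average linkage, cut at
the last merge into two clusters, misclassification minimized over the
label swap; expression PCA centres features without scaling. cis-eQTL
windows are gene body ± 1 Mb (TSS ± 1 Mb behind a flag); Spearman p uses
the t approximation for n ≥ 10 and exact pairing enumeration below
that; direction labels cross the CLR_C minor-allele log-odds sign
(risky/protective) with the correlation sign (up/down), zero in either
component giving "unclassified".

## Synthetic cohorts

`simulate_cohort` draws a population pool 10× the target cohort,
genotypes each gene as a latent AR(1) Gaussian block (correlation
`ld_rho`, default 0.3) thresholded to Hardy–Weinberg margins at a MAF
uniform on [0.05, 0.5], gives disease a logistic liability with the
planted per-allele log-odds (default ln 1.7 at five causal SNPs in each
of two causal genes) plus 0.1 log-odds per kg/m² of BMI around a 20%
baseline prevalence, ascertains cases among the affected, and matches
each to an unaffected control of the same gender within ±5 years by
nearest age. Missing calls are uniform at 0.2% — typical array
missingness, under which nearly all samples pass the 0.99 call-rate
gate. Genotypes are recoded to the cohort's empirically minor allele so
the frequency-forced PED coding round-trips exactly. All randomness
flows from one seeded generator; identical configs are byte-identical.

`simulate_expression` gives each gene a baseline intensity (SD 2 across
genes, which induces the between-sample rank correlation real arrays
show), unit-SD noise, a linear BMI nuisance, and shifts planted genes
between groups by `effect_sd_units` (default 2) noise SDs, up or down
with equal probability per gene.

Not emulated: recombination-map LD beyond one gene, population
substructure or admixture, genotyping-batch artifacts, probe-level
expression noise, and linkage between the genetic and expression
effect sizes. Passing tests therefore demonstrate correctness and
calibration of the operators, not field performance on real cohorts.

## Problem sizes used in checks

Replicated analyses are run at desk scale: null calibration of the
permutation machinery on 200 genes × 200 pairs at B = 1,000; recovery
power on 50 replicates of 400-pair cohorts at B = 500 (the production
default is B = 10,000); Monte-Carlo verification of the truncated-
product null at 10⁶ draws per gene size. The analysis drivers use
B = 2,000.

## Known limitations

The analytic TPM null assumes independent SNPs; step 1 is therefore a
screening device only and final inference rests on the permutation
step. The pair-difference reduction is exact only for 1:1 matching.
Expression features are keyed by gene symbol with one feature per gene
in the simulator; multi-probe summarization (maximum-variance probe) is
the convention for real arrays but is not exercised by the generator.
X-chromosome handling, relatedness screening and genotype imputation
are out of scope.
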