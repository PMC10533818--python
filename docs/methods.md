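# Methods

## Scientific setting

Breast-cancer polygenic risk scores (PRS) summarize static germline risk.
DNA methylation at methylation quantitative trait loci (mQTLs) — CpGs
whose methylation level is genetically coupled to PRS variants — sits at
the interface of genotype and environment: the genotype sets a baseline,
while age, body-mass index, and exposures move methylation around it.
`widqt` implements the full analysis built on that idea: a weighted
methylation index over mQTL CpGs measured in a surrogate tissue
(cervical, buccal, blood as proxies for breast), a SNP PRS from
effect-allele dosages, and their combination into median-split risk
groups quantified by exact conditional odds ratios.

## The methylation risk index

Given beta values β_ij ∈ [0,1] at CpG i for subject j, the index is

    score_j = ( Σ_i w_i β_ij − μ ) / σ

where the weights w_i come from a penalized logistic regression of case
status on the mQTL-CpG betas and (μ, σ) are the mean and sample SD of the
raw weighted sum over the discovery set, so discovery scores have zero
mean and unit SD by construction. The logistic intercept is dropped from
scoring: centring by μ removes location anyway. Weights act on the beta
scale directly (no M-value transform).

Training protocol:

1. Fit L1 (lasso) and L2 (ridge) logistic regressions on the
   discovery-train split over a descending lambda path (30 points,
   geometric, from the analytic all-zero threshold λ_max =
   max_i |x_iᵀ(y−ȳ)|/n down to λ_max/100). Lambda is chosen to minimize
   the mean 10-fold cross-validated binomial deviance; folds are
   stratified by case status and seeded.
2. The candidate with the higher AUC on the internal validation split is
   selected; ties break toward fewer non-zero coefficients.
3. The selected penalty is refit on the full discovery set (CV repeated
   there) and (μ, σ) are fixed on the discovery scores.

The path solver is a coordinate-descent/IRLS implementation with
soft-thresholding, active-set iteration, warm starts down the path, and
internal column centring. Centring matters for methylation mixtures:
every CpG loads on the immune-cell fraction, and with an uncentred design
the intercept and that shared factor interact so badly that coordinate
descent needs thousands of sweeps. Ridge uses damped IRLS-Newton with an
explicit Hessian solve, which is exact and cheap at ≤ a few hundred
features. The solver is validated against R glmnet in the test suite
(agreement ≤ 5e-3 in every coefficient at matched lambdas).

Numerical choices: convergence is declared when the largest coefficient
update falls below 1e-4 (CV fits) or 1e-6 (final fits); IRLS weights are
floored at 1e-5; an all-zero final model (σ = 0) is an error rather than
a silently degenerate index.

## Polygenic risk score and genotype QC

PRS_j = Σ_i β̂_i x_ij over effect-allele dosages x ∈ {0,1,2}, with β̂ the
published per-SNP log odds ratios. QC removes subjects with call rate
< 95% first, then SNPs with missing rate > 5%, minor-allele frequency
< 1%, or exact Hardy-Weinberg p < 5e-6. The HWE test conditions on allele
counts and enumerates all heterozygote counts of matching parity, summing
the probabilities of configurations no more likely than the observed one.
Missing dosages at scoring time are imputed as 2 × the cohort
effect-allele frequency — the standard scoring fallback when upstream
imputation is out of scope. VCF input is harmonized to the weight table's
effect allele (REF/ALT flips and strand complements handled;
strand-ambiguous A/T and C/G variants are used as-is with a warning).

## Risk groups and median-unbiased odds ratios

Subjects are labelled high on a score iff it exceeds the median of that
score within the same set (discovery and validation medians are never
pooled); ties at the median go low. The PRS and index labels are crossed
into four groups with low/low as reference.

For a 2×2 table with margins fixed, the exposed-case count follows
Fisher's noncentral hypergeometric distribution with noncentrality ψ (the
conditional odds ratio). The median-unbiased estimate is the ψ at which
the mid-p tail probability of the observed count equals 1/2 — with the
mid-p correction the upper- and lower-tail equations coincide, so the
estimate is the (trivial) average of the two roots. 95% limits invert
each mid-p tail at 0.025; the two-sided p-value is twice the smaller
mid-p tail at ψ = 1. Roots are found by bisection on log ψ to 1e-8, with
brackets expanded from the Haldane-corrected cross-product ratio. Tables
whose observed count sits on the support boundary give estimates of 0 or
∞ with the corresponding one-sided interval; a margin-degenerate table
(support is a single point) carries no information about ψ and returns
OR 1 with p 1.

A caution discovered while testing: the folk claim that the
median-unbiased estimate always lies between the conditional MLE and the
crude cross-product ratio is false for small tables (e.g. cells
1/4/9/16 give MUE 0.494 vs cMLE 0.455 and crude 0.444). The estimator is
verified instead against an independent fine-grid inversion of the
noncentral hypergeometric tail built from log-binomial sums.

## Permutation null for index specificity

To ask whether mQTL CpGs carry more risk information than arbitrary CpGs,
the lasso training is repeated on panels of CpGs sampled without
replacement from the non-mQTL pool, each permutation retraining on the
discovery-train split (its own child seed re-randomizes the CV folds) and
scoring the external validation set. The result is a null AUC
distribution with its median and central 95% band. The index is specific
if its own validation AUC clears the upper band. Training uses the
discovery-train split only — mirroring where the real index's weights
came from — rather than the full discovery set; the distinction is
immaterial for the null's location but keeps the comparison like-for-like.

## Evaluation utilities

AUC is the Mann-Whitney concordance probability with ties counted 1/2;
its 95% CI uses the DeLong placement-value variance. Unpaired group
comparisons default to Welch's t-test; paired comparisons use the
Wilcoxon signed-rank test with the exact null distribution for ≤ 25
non-zero differences (the paired designs this analysis cares about have
n = 9 and 11) and a continuity-corrected normal approximation above.
Paired reduction rates count strictly decreased pairs; exact ties are
non-reductions. Covariate associations are per-group Pearson correlations
with t-distribution p-values.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not array physics. Per subject: dosages ~ Binomial(2, MAF) independently
per SNP (Hardy-Weinberg); epithelial logit-methylation at CpG i is

    baseline_i + Σ_mQTL effect·dosage + case_effect_i·case
    + age_effect_i·(age−mean) + bmi_effect_i·(bmi−mean) + N(0, noise_sd)

and the observed beta mixes epithelial and immune states linearly on the
beta scale by the subject's immune fraction f:
beta = (1−f)·logistic(ℓ) + f·logistic(immune_baseline). Additive Gaussian
noise on the logit scale before mixing keeps betas in [0,1] without
truncation (a logit-normal methylation model). Covariates are centred
before effects are applied, so baselines are population-mean logits. One
global seed expands into per-stage child streams (panel, genotypes,
phenotypes, per-tissue methylation).

Default design — the conditions under which all calibration claims are
made: 50 SNPs (MAF uniform 0.1–0.5, PRS weights N(0, 0.1²)); 120 mQTL
CpGs (one SNP each, per-allele logit effect ±0.5) among 880 background
CpGs; 600/300/300 subjects in discovery-train / internal-validation /
validation with 35% cases per set; case effect ±0.1 on the logit scale at
30 mQTL CpGs and nowhere else; age/BMI effects N(0, 0.01²) per CpG; logit
noise SD 0.5; immune fraction ~ Beta(1.5, 4.5). The case-effect magnitude
was set so the trained index's validation AUC lands in the ~0.70
operating regime the real cervical-sample index reports — a deliberately
realistic, far-from-separable difficulty — and the desk-scale 120/880
panel mirrors the real 704-of-822 mQTL structure at roughly one-sixth
size. Because case signal exists only at mQTL CpGs, the random-CpG
permutation null is exactly calibrated (median AUC ≈ 0.5) by
construction.

What the generator does not emulate: probe chemistry and detection noise,
batch/chip effects, linkage disequilibrium between SNPs, correlated CpG
co-methylation beyond the shared immune-fraction factor, and non-linear
covariate effects. Passing tests therefore show the pipeline recovers the
structure it models — they do not certify performance on real arrays.

## Problem sizes used by the test suite

Unit tests run on cohorts of 200–400 subjects with 40–200 CpGs. The
calibration tests use the full default design above: 10 seeded cohorts
for signal recovery, a 100-permutation null (panels of 120 CpGs), and 20
seeded null cohorts (case effect zero). The permutation count is scaled
down from the 10,000 used at full scale; the full-scale run stays
available through `widqt permute --n-perm 10000`.

## Known limitations

- The exact-OR machinery targets single 2×2 comparisons; no
  covariate-adjusted (regression) odds ratios.
- PRS weights are consumed as given; no re-estimation, no LD awareness.
- The immune fraction is an input (one value per subject), not estimated
  from methylation, and the generator shares it across tissues.
- The published 104-CpG coefficient table is not bundled; a trained model
  in the same TSV + JSON format can be loaded and applied with
  `widqt score`.
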