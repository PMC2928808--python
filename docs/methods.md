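# Methods

`transrep` implements the statistical machinery of a trans-ethnic
replication study of common disease risk variants: a fixed panel of SNPs
discovered in one population is tested for association in several
population strata of a single case-control study, the evidence is
synthesised across strata, and the variants are aggregated into a genetic
risk score whose population distribution is compared between groups. The
packaged defaults describe a five-population type 2 diabetes (T2D) study
(European American, African American, Latino, Japanese American, Native
Hawaiian; 6,142 cases / 7,403 controls) with a 19-SNP panel.

## Association models

Per-SNP association uses unconditional logistic regression of case status
on the risk-allele dosage (0/1/2), giving a per-allele (log-additive) odds
ratio. Adjusters follow the study design: indicator terms for quartiles of
age and of BMI, sex, and ethnicity indicators in pooled analyses. Quartile
cutpoints are computed within each analysis sample (cases and controls
combined; pooled models use pooled cutpoints), with values tied to a
cutpoint placed in the lower quartile. Single-SNP models are complete-case
for that SNP; score-level imputation (below) never feeds single-SNP fits.
A genotype-category model (heterozygote and homozygote indicators versus
non-carriers) is provided to inspect dosage monotonicity, and the two
linked KCNQ1 variants are fitted jointly so each is adjusted for the
other.

Fitting is maximum likelihood via Newton-Raphson (statsmodels `Logit`,
`tol=1e-10`, at most 100 iterations). The module adds two diagnostics on
top: a rank check that names collinear design columns (via the small
singular directions of the design), and a separation check that rejects
fits whose largest |log-odds| exceeds 15 — at that magnitude the MLE is
effectively infinite and Wald output meaningless. Monomorphic SNPs return
a "not estimable" result rather than raising, since a panel scan must
continue past them. Wald tests and Wald 95% CIs are reported because the
study's OR/CI/P triplets are Wald-shaped; likelihood-ratio p-values are
available for nested comparisons.

## Cross-population synthesis

For one stratum's panel fits the package counts how many ORs exceed 1
(strictly; exact ties at 1.0 are tallied separately because on unrounded
estimates they indicate a degenerate fit) and how many Wald p-values fall
below a nominal level. Both counts get exact binomial tail probabilities:
under the null, direction is a fair coin (p = 1/2) and nominal
significance occurs at rate alpha. Heterogeneity of a SNP's per-allele
effect across k strata defaults to Cochran's Q on the stratum log-ORs with
inverse-variance weights, referred to chi-square with k-1 degrees of
freedom (4 df for five strata); a dosage-by-ethnicity interaction
likelihood-ratio test with the same df is available and agrees with Q to
within 10% on large strata. A Bonferroni-adjusted heterogeneity column
over the panel's tests is reported but never used to filter.

## Genotype quality control

Call rate is the fraction of non-missing genotypes per SNP within any
group. Hardy-Weinberg testing among controls uses the exact conditional
test: conditioning on the observed allele totals, the p-value sums the
probabilities of all heterozygote counts no more probable than the
observed one (two-sided by probability ordering, no mid-p). Probabilities
are computed in log space with a relative tie guard of 1e-10 so that
mathematically tied states always enter the tail together; SNPs with one
allele absent return p = 1 with a monomorphic flag. Subjects missing more
than 5 of the panel's genotypes are removed (the study's rule); SNPs below
95% call rate or with control HWE p < 0.01 are flagged in the report but
never dropped, mirroring the study, which kept all 19 SNPs.

## Risk score

The aggregate score is the per-subject sum of risk-allele dosages over the
included SNPs. The default inclusion list is the panel minus the FTO
variant (18 SNPs): the FTO association with T2D is mediated by adiposity,
and the reconstruction 2 x sum(RAF) over these 18 SNPs reproduces the
published per-stratum mean allele counts (18.8 / 20.2 / 18.6 / 18.1 and
pooled 18.5 at one decimal) while including FTO does not. The source text
speaks of "19 risk-associated alleles", which the arithmetic contradicts;
the inclusion list is configurable. The Japanese-American reconstruction
gives 17.14 (prints 17.1) against a published 17.2 — consistent with the
published mean having been computed on raw data while the published
frequencies are rounded to two decimals.

A missing genotype contributes twice the SNP's risk-allele frequency in
the subject's stratum, with frequencies computed from the analysis sample
(cases + controls): this choice makes the imputation exactly
mean-preserving (the stratum mean score equals 2 x sum of stratum RAFs
identically) and is what reproduces the published means from the published
frequencies. An optional weighted score multiplies each allele by the log
of its published per-allele OR before summing. With the pooled study ORs
as weights, the weighted and unweighted scores correlate at r of about
0.85-0.88 per stratum — the theoretical plug-in value
sum(w v)/sqrt(sum(v) sum(w^2 v)) with v = 2p(1-p); higher correlations
require the discovery-study weight set, which the packaged data does not
contain.

Score association mirrors the per-SNP model with the score as exposure.
Quartile analyses define cutpoints separately within each population
(combined cases + controls by default), use the lowest quartile as
referent, and send boundary ties to the lower quartile — integer scores
force an explicit tie rule.

## Risk-distribution model

For one population, the distribution of total risk-allele counts among
controls is mapped through

    logRR = (RA - RA0) * ln(OR_i)

with OR_i the population's fitted per-allele score OR and RA0 a common
centering constant, so logRR = 0 at the reference count. RA0 defaults to
the pooled control mean computed from the data (the source study fixes
18.5); all location comparisons are invariant to a common center. Scores
are binned to the nearest integer allele count for the discrete support.
All statistics (mean, SD, overlap) are computed on the discrete
distribution — the mean logRR equals (mean RA - RA0) ln(OR_i) exactly. The
overlap coefficient discretises two distributions onto a shared 400-bin
logRR grid and sums bin-wise minima. Smoothing (cubic smoothing spline on
the frequency polygon, clamped non-negative and renormalised; Gaussian KDE
as an alternative) is display-only and excluded from all statistics; with
fewer than four support points it falls back to discrete bars with a
warning.

## Power

Analytic power of the per-allele test uses the allele-counting normal
approximation: the case allele frequency implied by the control frequency
and the assumed OR on the odds scale, variance of the log allele-count OR
from expected counts under HWE (2N alleles per group), and

    power = Phi(-z_{a/2} + |ln OR|/SE) + Phi(-z_{a/2} - |ln OR|/SE),

which returns exactly alpha at OR = 1. A logistic-Wald variant derives the
SE from the expected information of the dosage model; the two agree within
0.02 at moderate effects, and both track a simulation oracle (empirical
rejection rate over 2,000 replicates) within 0.03 at the tested parameter
triples.

## Synthetic cohorts

The generator draws, per stratum: genotypes as independent Binomial(2,
RAF) per SNP (Hardy-Weinberg by construction; SNPs are unlinked, matching
a panel spread across loci — an optional haplotype-correlation parameter
links the two KCNQ1 variants to exercise the co-adjusted model); age and
BMI as truncated normals and sex as Bernoulli, parameterised per stratum
from the study's descriptive table; and disease from a logistic model
whose linear predictor sums dosage times log generative OR plus covariate
effects (defaults: odds ratio 1.5 per BMI quartile step, 1.1 per age
quartile step, no sex effect — the study reports cases heavier but states
only the adjustment, not effect sizes). The intercept is solved by
bisection (tolerance 1e-6) so the marginal prevalence matches a target,
default 0.10 — a realistic T2D prevalence for a cohort aged 45-77.
Case-control sampling is retrospective thinning of this prospective pool:
the requested cases are drawn, then controls are frequency-matched to the
sampled cases' 5-year age bands with largest-remainder rounding. Finally
each genotype is independently set missing at a configurable rate
(default 2%, consistent with all call rates exceeding 95%).

The packaged design (`data/mec_t2d_study.yaml`) uses the published
stratum sizes, ethnic-specific risk-allele frequencies, and
ethnic-specific per-allele odds ratios as generative parameters.

What the generator does *not* emulate: linkage disequilibrium beyond the
KCNQ1 pair, admixture or population stratification (an ancestry covariate
column is supported but not generated), genotyping batch effects,
case-status misclassification, and correlation between genotype and
covariates. Passing recovery tests therefore demonstrate the estimators'
correctness under the study's stated sampling design, not robustness to
confounding that the real study may have faced.

## Test problem sizes

The acceptance-grade checks run at the sizes the package documents as its
defaults: 100 replicates of the full published design (6,142 cases /
7,403 controls across five strata) for CI coverage of the generative
log-ORs, the pooled score OR band, and the qualitative risk-distribution
comparisons; 500 null replicates of a five-stratum 250/250 design for the
type-I error of the dosage and heterogeneity tests; and 2,000-replicate
oracles for power. Unit-level simulations use smaller draws with fixed
seeds.

## Known limitations

* Real-data adjusted ORs (for example TCF7L2 pooled 1.36) are reference
  anchors only: they cannot be reproduced exactly without the original
  subject-level data.
* The exact form of the study's 4-df heterogeneity test is not documented;
  Cochran's Q is the default here because it matches the degrees of
  freedom and needs only per-stratum fits.
* The discovery-literature odds ratios behind the study's weighted score
  and power table are not in the packaged data; the study's own pooled ORs
  stand in as the default weight/assumption set.
* Multi-allelic or half-missing genotypes are not representable; the
  cohort format forbids them.
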