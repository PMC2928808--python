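# transrep

Trans-ethnic replication analysis of common disease risk variants.

When a panel of GWAS-validated risk SNPs is genotyped in a multiethnic
case-control study, three questions follow: does each variant replicate —
in direction and significance — in populations other than the one it was
discovered in; do the per-allele effects differ between populations; and
how much disease risk does the panel convey, and does its distribution
differ between populations enough to explain disparities in prevalence?
`transrep` implements this analysis as a tested, reusable pipeline for
epidemiologists and statistical geneticists, with a synthetic-cohort
generator so every stage can be exercised and calibrated without access
to subject-level data. The packaged defaults describe a five-population
type 2 diabetes study (European American, African American, Latino,
Japanese American, Native Hawaiian; 6,142 cases / 7,403 controls; 19
SNPs).

## The statistics

* **Per-SNP association.** Unconditional logistic regression of case
  status on risk-allele dosage d ∈ {0,1,2}: the per-allele odds ratio is
  exp(β) from `logit P(D) = β0 + β·d + γ·X`, with X the study adjusters —
  age quartiles, BMI quartiles, sex, and ethnicity indicators in pooled
  fits. The two KCNQ1 variants are co-modelled so each is adjusted for
  the other.
* **Direction consistency.** With n SNPs, the count k of ORs > 1 gets the
  exact binomial tail P(X ≥ k | n, ½); counts of nominally significant
  SNPs get P(X ≥ k | n, α).
* **Heterogeneity.** Cochran's Q on stratum log-ORs θ̂_i with weights
  w_i = 1/SE_i²: Q = Σ w_i (θ̂_i − θ̄)² ~ χ²(k−1) under homogeneity
  (4 df for five strata); an interaction LRT with the same df is offered.
* **Hardy-Weinberg QC.** Exact conditional test among controls (tail of
  heterozygote counts no more probable than observed), call rates, and
  the subject-exclusion rule "missing more than 5 panel SNPs".
* **Risk score.** RA = Σ_j w_j d̃_j over the 18 score SNPs (panel minus
  FTO), w_j = 1 or log published OR; a missing dosage is imputed as
  2 × RAF of its SNP in the subject's ethnic group, which is exactly
  mean-preserving. Per-allele and population-specific quartile ORs follow
  the association model.
* **Risk distribution.** Control allele counts mapped through
  `logRR = (RA − RA0)·ln(OR_i)` with OR_i the stratum's per-allele score
  OR and RA0 the pooled control mean (18.5 in the source study); means,
  SDs and overlap coefficients compare populations, a smoothing spline is
  display-only.
* **Power.** Allele-counting normal approximation for the per-allele
  test, validated against simulation.

## Worked example

Simulate the packaged study design (published stratum sizes, risk-allele
frequencies and per-allele ORs as generative parameters), run QC, and ask
the headline questions:

```python
from transrep.synthetic import SimulationSpec, simulate_study
from transrep.qc import apply_qc
from transrep.association import snp_dosage_assoc
from transrep.crosspop import snp_heterogeneity
from transrep.score import ScoreConfig, compute_scores, score_summary_table

spec = SimulationSpec.from_study(seed=17)
cohort, qc_report = apply_qc(simulate_study(spec, seed=17))

t = snp_dosage_assoc(cohort, "rs7903146").primary   # TCF7L2, pooled
print(f"OR {t.or_:.2f} ({t.ci_low:.2f}-{t.ci_high:.2f}), P = {t.wald_p:.2g}")
het = snp_heterogeneity(cohort, "rs7903146")
print(f"Q = {het.q_stat:.2f} on {het.df} df, P_het = {het.p_het:.2f}")

scored = compute_scores(cohort, ScoreConfig())
print(score_summary_table(cohort, scored).round(3).to_string(index=False))
```

prints

```
OR 1.41 (1.32-1.51), P = 1.8e-25
Q = 14.49 on 4 df, P_het = 0.01
         stratum  mean_ra  min_ra  max_ra    or  ci_low  ci_high     p     n
EuropeanAmerican   18.808    11.0    27.0 1.075   1.031    1.121 0.001  1539
 AfricanAmerican   20.320    12.0    29.0 1.077   1.041    1.113 0.000  2546
          Latino   18.867     8.0    28.0 1.111   1.085    1.139 0.000  4404
JapaneseAmerican   17.575     8.0    26.0 1.187   1.153    1.223 0.000  3497
  NativeHawaiian   18.320    12.0    26.0 1.095   1.049    1.142 0.000  1559
          Pooled   18.737     8.0    29.0 1.116   1.100    1.132 0.000 13545
```

The simulated TCF7L2 per-allele OR (1.41) recovers its generative value
(the published pooled 1.36) within its CI. The score table reads as in
the source study: mean total risk alleles per stratum (African Americans
highest, Japanese Americans lowest), and an adjusted per-allele score OR
per stratum — largest in Japanese Americans, whose generative per-SNP
effects are strongest.

The same stages are available from the shell:

```
transrep simulate --out cohort.tsv --seed 17
transrep qc cohort.tsv
transrep assoc cohort.tsv --out association.tsv
transrep consistency association.tsv
transrep het cohort.tsv
transrep score cohort.tsv
transrep riskdist cohort.tsv
transrep power --n-cases 533 --n-controls 1006 --raf 0.27 --or 1.37
transrep run --config run.yaml --out results/
```

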