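# Study parameters of the multiethnic type 2 diabetes (T2D) case-control
# replication study that this package's default synthetic cohorts emulate:
# per-stratum sample sizes, published ethnic-specific risk-allele frequencies
# (raf) and per-allele odds ratios (or_gen) for the 19-SNP panel, and
# covariate distributions summarising the descriptive cohort characteristics.
# or_gen values double as the generative per-allele odds ratios of the
# synthetic disease model.
baseline_prevalence: 0.10
missing_rate: 0.02
age_match_band_years: 5
age_range: [45, 77]
bmi_quartile_or: 1.5
age_quartile_or: 1.1
sex_or: 1.0
strata:
  EuropeanAmerican:
    n_cases: 533
    n_controls: 1006
    age_mean: 57.9
    age_sd: 8.2
    bmi_mean: 24.7
    bmi_sd: 4.0
    female_fraction: 0.49
    raf:
      rs10923931: 0.12
      rs7578597: 0.90
      rs1801282: 0.89
      rs4607103: 0.73
      rs4402960: 0.31
      rs10010131: 0.59
      rs7754840: 0.29
      rs864745: 0.51
      rs13266634: 0.68
      rs2383208: 0.81
      rs1111875: 0.61
      rs7903146: 0.27
      rs12779790: 0.17
      rs2237895: 0.42
      rs2237897: 0.95
      rs5219: 0.35
      rs7961581: 0.29
      rs8050136: 0.41
      rs4430796: 0.50
    or_gen:
      rs10923931: 0.84
      rs7578597: 1.42
      rs1801282: 1.26
      rs4607103: 1.11
      rs4402960: 1.02
      rs10010131: 1.18
      rs7754840: 1.26
      rs864745: 0.98
      rs13266634: 1.28
      rs2383208: 1.35
      rs1111875: 0.93
      rs7903146: 1.55
      rs12779790: 1.02
      rs2237895: 0.98
      rs2237897: 0.86
      rs5219: 1.24
      rs7961581: 1.03
      rs8050136: 0.89
      rs4430796: 0.96
  AfricanAmerican:
    n_cases: 1077
    n_controls: 1469
    age_mean: 60.2
    age_sd: 8.4
    bmi_mean: 27.0
    bmi_sd: 5.0
    female_fraction: 0.59
    raf:
      rs10923931: 0.29
      rs7578597: 0.75
      rs1801282: 0.97
      rs4607103: 0.70
      rs4402960: 0.49
      rs10010131: 0.66
      rs7754840: 0.55
      rs864745: 0.73
      rs13266634: 0.89
      rs2383208: 0.81
      rs1111875: 0.74
      rs7903146: 0.28
      rs12779790: 0.14
      rs2237895: 0.20
      rs2237897: 0.92
      rs5219: 0.09
      rs7961581: 0.23
      rs8050136: 0.43
      rs4430796: 0.65
    or_gen:
      rs10923931: 1.10
      rs7578597: 1.04
      rs1801282: 1.95
      rs4607103: 1.03
      rs4402960: 1.14
      rs10010131: 0.94
      rs7754840: 1.03
      rs864745: 1.16
      rs13266634: 1.21
      rs2383208: 1.14
      rs1111875: 1.10
      rs7903146: 1.32
      rs12779790: 1.09
      rs2237895: 1.04
      rs2237897: 1.13
      rs5219: 1.03
      rs7961581: 0.92
      rs8050136: 1.07
      rs4430796: 1.10
  Latino:
    n_cases: 2220
    n_controls: 2184
    age_mean: 59.4
    age_sd: 7.0
    bmi_mean: 26.2
    bmi_sd: 4.0
    female_fraction: 0.52
    raf:
      rs10923931: 0.09
      rs7578597: 0.94
      rs1801282: 0.90
      rs4607103: 0.69
      rs4402960: 0.27
      rs10010131: 0.71
      rs7754840: 0.31
      rs864745: 0.61
      rs13266634: 0.75
      rs2383208: 0.85
      rs1111875: 0.63
      rs7903146: 0.23
      rs12779790: 0.17
      rs2237895: 0.40
      rs2237897: 0.76
      rs5219: 0.37
      rs7961581: 0.21
      rs8050136: 0.27
      rs4430796: 0.42
    or_gen:
      rs10923931: 1.17
      rs7578597: 1.12
      rs1801282: 1.03
      rs4607103: 0.99
      rs4402960: 1.05
      rs10010131: 1.15
      rs7754840: 1.09
      rs864745: 1.30
      rs13266634: 1.11
      rs2383208: 1.15
      rs1111875: 1.03
      rs7903146: 1.31
      rs12779790: 1.19
      rs2237895: 1.15
      rs2237897: 1.23
      rs5219: 1.09
      rs7961581: 1.03
      rs8050136: 1.02
      rs4430796: 0.96
  JapaneseAmerican:
    n_cases: 1736
    n_controls: 1761
    age_mean: 59.2
    age_sd: 8.3
    bmi_mean: 23.6
    bmi_sd: 3.4
    female_fraction: 0.44
    raf:
      rs10923931: 0.02
      rs7578597: 0.99
      rs1801282: 0.96
      rs4607103: 0.61
      rs4402960: 0.30
      rs10010131: 0.98
      rs7754840: 0.40
      rs864745: 0.77
      rs13266634: 0.60
      rs2383208: 0.56
      rs1111875: 0.28
      rs7903146: 0.04
      rs12779790: 0.17
      rs2237895: 0.35
      rs2237897: 0.62
      rs5219: 0.35
      rs7961581: 0.21
      rs8050136: 0.20
      rs4430796: 0.36
    or_gen:
      rs10923931: 1.00
      rs7578597: 1.10
      rs1801282: 1.05
      rs4607103: 1.05
      rs4402960: 1.24
      rs10010131: 1.45
      rs7754840: 1.37
      rs864745: 1.19
      rs13266634: 1.18
      rs2383208: 1.26
      rs1111875: 1.21
      rs7903146: 1.74
      rs12779790: 1.01
      rs2237895: 1.12
      rs2237897: 1.26
      rs5219: 1.26
      rs7961581: 1.00
      rs8050136: 1.04
      rs4430796: 1.18
  NativeHawaiian:
    n_cases: 576
    n_controls: 983
    age_mean: 55.6
    age_sd: 7.3
    bmi_mean: 27.1
    bmi_sd: 5.2
    female_fraction: 0.52
    raf:
      rs10923931: 0.05
      rs7578597: 0.97
      rs1801282: 0.93
      rs4607103: 0.72
      rs4402960: 0.27
      rs10010131: 0.81
      rs7754840: 0.52
      rs864745: 0.75
      rs13266634: 0.62
      rs2383208: 0.74
      rs1111875: 0.28
      rs7903146: 0.14
      rs12779790: 0.18
      rs2237895: 0.33
      rs2237897: 0.78
      rs5219: 0.37
      rs7961581: 0.29
      rs8050136: 0.23
      rs4430796: 0.31
    or_gen:
      rs10923931: 0.76
      rs7578597: 1.65
      rs1801282: 1.14
      rs4607103: 0.98
      rs4402960: 1.17
      rs10010131: 1.27
      rs7754840: 1.39
      rs864745: 1.13
      rs13266634: 1.04
      rs2383208: 1.02
      rs1111875: 0.93
      rs7903146: 1.12
      rs12779790: 1.16
      rs2237895: 1.16
      rs2237897: 1.06
      rs5219: 1.03
      rs7961581: 1.12
      rs8050136: 1.01
      rs4430796: 1.09
pooled:
  raf:
    rs10923931: 0.11
    rs7578597: 0.91
    rs1801282: 0.93
    rs4607103: 0.68
    rs4402960: 0.33
    rs10010131: 0.76
    rs7754840: 0.40
    rs864745: 0.68
    rs13266634: 0.72
    rs2383208: 0.75
    rs1111875: 0.52
    rs7903146: 0.19
    rs12779790: 0.17
    rs2237895: 0.34
    rs2237897: 0.79
    rs5219: 0.31
    rs7961581: 0.23
    rs8050136: 0.30
    rs4430796: 0.45
  or:
    rs10923931: 1.06
    rs7578597: 1.13
    rs1801282: 1.13
    rs4607103: 1.02
    rs4402960: 1.13
    rs10010131: 1.11
    rs7754840: 1.20
    rs864745: 1.20
    rs13266634: 1.15
    rs2383208: 1.18
    rs1111875: 1.07
    rs7903146: 1.36
    rs12779790: 1.10
    rs2237895: 1.11
    rs2237897: 1.21
    rs5219: 1.15
    rs7961581: 1.01
    rs8050136: 1.02
    rs4430796: 1.05
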