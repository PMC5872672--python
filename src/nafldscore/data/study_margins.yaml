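# Margins scenario for the three study groups (n = 90 / 93 / 107).
# Genotype class counts are (ancestral hom, heterozygote, minor hom) per
# locus; the NAFLD group is split into its fibrosis subgroups (whose
# per-locus counts sum exactly to the whole-group margins).  Age/BMI are
# truncated-normal moments (age >= 18 y, BMI >= 15 kg/m2); sex and T2DM are
# Bernoulli fractions.
mode: margins
groups:
  - group: healthy
    n: 90
    age: {mean: 43.1, sd: 11.9}
    bmi: {mean: 25.2, sd: 4.6}
    male_fraction: 0.466
    t2dm_prevalence: 0.07
    genotype_counts:
      rs738409: [53, 30, 7]
      rs58542926: [79, 11, 0]
      rs3750861: [79, 11, 0]
      rs4880: [26, 42, 22]
      rs13412852: [38, 41, 11]
  - group: nafld
    label: nafld_f01
    n: 51
    age: {mean: 46.7, sd: 13.1}
    bmi: {mean: 28.5, sd: 3.8}
    male_fraction: 0.647
    t2dm_prevalence: 0.314
    fibrosis_counts: {F0: 9, F1: 42}
    genotype_counts:
      rs738409: [19, 19, 13]
      rs58542926: [42, 9, 0]
      rs3750861: [45, 6, 0]
      rs4880: [9, 27, 15]
      rs13412852: [26, 18, 7]
  - group: nafld
    label: nafld_f23
    n: 42
    age: {mean: 57.5, sd: 11.0}
    bmi: {mean: 30.8, sd: 4.2}
    male_fraction: 0.548
    t2dm_prevalence: 0.619
    fibrosis_counts: {F2: 22, F3: 20}
    genotype_counts:
      rs738409: [11, 17, 14]
      rs58542926: [32, 8, 2]
      rs3750861: [35, 7, 0]
      rs4880: [11, 21, 10]
      rs13412852: [19, 19, 4]
  - group: cirrhosis
    n: 107
    age: {mean: 66.2, sd: 9.8}
    bmi: {mean: 31.2, sd: 5.2}
    male_fraction: 0.533
    t2dm_prevalence: 0.664
    genotype_counts:
      rs738409: [20, 44, 43]
      rs58542926: [79, 27, 1]
      rs3750861: [83, 23, 1]
      rs4880: [30, 49, 28]
      rs13412852: [49, 50, 8]
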