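# Methods

## Data model

A cohort is a table of subjects with a group label (`healthy`, `nafld`,
`cirrhosis`), covariates (age in years, sex, BMI in kg/m², type-2 diabetes
yes/no, optional fibrosis stage F0–F3 for NAFLD subjects) and one diploid
genotype call per panel SNP.  The panel fixes each locus's ancestral and
minor (risk) allele a priori — G for PNPLA3 rs738409, T for the others —
rather than re-estimating the minor allele from data, where sampling noise
in small groups could flip a coding.  Genotype strings are unphased and
stored canonically (ancestral allele first), so each maps to a
minor-allele count 0/1/2.  Missing calls (`NA`) exclude a subject from any
analysis involving that SNP; the score requires complete genotypes at the
score's SNPs and lists excluded subjects.  No imputation is attempted:
there is no missingness model to support one.

## Descriptive statistics

Minor-allele frequency is (het + 2·hom_minor)/(2n); reports round to two
decimals (halves away from zero).  Group comparisons use the plain Pearson
chi-square — Σ(O−E)²/E, no continuity correction, p from χ² on
(r−1)(c−1) df — for categorical variables and Kruskal-Wallis
(tie-corrected, via scipy) for continuous ones, two-sided at α = 0.05.
When any expected cell count is below 5 (the TM6SF2/KLF6 TT cells are that
sparse) the test still runs but attaches a warning; it does not silently
switch to an exact test, which would change the reported p-values.
Pairwise allele-frequency contrasts are 2×2 allele-count chi-squares — an
interpretation, since the source tables do not state the pairwise test
used.

## Logistic engine

`LogisticIRLS` is unpenalized maximum likelihood via Newton/IRLS:
deviance-change stopping at 1e-8 within 100 iterations, standard errors
from the inverse observed information at the MLE, AIC = 2k − 2ℓ, Wald
odds-ratio intervals exp(β̂ ± z·se).  Frequency weights allow grouped
(contingency-table) data, where the univariable fit reproduces the
closed-form ln(ad/bc) and Woolf SE — the equivalence is enforced to 1e-6
over every 2×2 table with cells 1..30 in the test suite.

Degenerate inputs fail loudly rather than returning unstable numbers:
rank-deficient designs (duplicated or collinear columns) and single-class
outcomes are errors, and separation — detected as any *slope* coefficient
exceeding 15 in absolute value during iteration — raises a dedicated
error.  The guard deliberately exempts constant (intercept) columns: with
age and BMI entered uncentered, the intercept of an adjusted model
legitimately reaches magnitudes of 30+ (it absorbs the covariate
location), while a slope of ±15 on a genotype, score or indicator column
(an odds ratio beyond e¹⁵) only arises when the MLE is diverging.

## Score construction

Coding selection fits case status ~ intercept + encoded genotype per
candidate scheme (additive, dominant, recessive) on the derivation
contrast (NASH cirrhosis vs noncirrhotic NAFLD by default) and keeps the
scheme with minimal AIC.  Two situations make a scheme unavailable rather
than erroneous: a constant encoding (e.g. recessive with no minor
homozygote in the contrast), and a quasi-separated one (e.g. a lone minor
homozygote who is a case), where the MLE and hence the AIC do not exist.
AIC ties — exact ties occur whenever two schemes produce identical encoded
vectors, e.g. dominant ≡ additive with no minor homozygotes — resolve to
additive, the least restrictive model for an ordinal genotype; the AIC
margin to the best competitor is recorded.

Raw weights default to the coefficients of one joint logistic model
containing all encoded score SNPs.  The phrase "coefficients of a logistic
regression analysis for the candidate genes" admits a univariable reading,
but univariable fits computed from the published margins do not reproduce
the published coefficients while a joint model is consistent with them; a
per-SNP univariable mode remains available (`weight_mode="univariable"`).
Weights standardize by their mean and round to the nearest unit, halves
away from zero.  The mean must be positive (risk-increasing orientation);
a SNP rounding to zero points is dropped from the score with a prominent
warning.  Scores are integers in [0, Σᵢ wᵢ·maxcodeᵢ]; two bandings are
provided, {0, 1–2, 3–4} and {0, 1, 2, 3+}, because published analyses use
both.

## Association models

For each pairwise group contrast, case membership is regressed on the
score (linear) or on score-band dummies against band "0" (categorical),
optionally adding age (continuous, uncentered), male sex, BMI (continuous,
uncentered) and T2DM.  Subjects missing an adjustment covariate are
excluded from adjusted models only, with counts reported; constant
covariates are dropped (they are collinear with the intercept), making
adjusted estimates equal unadjusted ones when covariates carry no
information.  No multiple-testing correction is applied across the model
family.  In the aggregate report a model that separates (plausible in the
sparsest band of the smallest contrast) has its cells marked unavailable
with the reason instead of aborting the bundle.

## Synthetic cohorts

**Margins mode** reproduces group-level marginal distributions: per-locus
genotype class counts (exactly — the class vector is materialized and
shuffled — or multinomially), truncated-normal age (≥ 18 y) and BMI
(≥ 15 kg/m²), Bernoulli sex and T2DM.  Loci are drawn independently; the
five panel SNPs sit in different genes on different chromosomes, and the
score model treats them as independent contributors.  The packaged
scenario encodes the three study groups, with the NAFLD group split into
fibrosis subgroups F0-1 (n=51) and F2-3 (n=42) whose per-locus counts sum
exactly to the whole-group margins.

**Liability mode** draws genotypes from Hardy-Weinberg proportions at
given allele frequencies and assigns case status Bernoulli(expit(η)),
η = intercept + Σᵢ βᵢ·codeᵢ + covariate terms.  It is the generative model
the score analysis presumes and supplies ground truth for recovery and
calibration experiments.  Defaults used in those experiments: allele
frequencies 0.3/0.1/0.1 (the range observed in the panel), per-point
log-odds 0.5, intercept −0.5 ≈ −0.5·E[score] so prevalence sits near 50%.

What margins-mode cohorts deliberately do **not** model: linkage
disequilibrium, within-subject correlation between loci beyond the
margins, covariate–genotype dependence, population stratification,
genotyping error.  Consequently, statistics that are functions of the
margins alone (allele frequencies, genotype tables, group score means —
the group mean is Σᵢ wᵢ·mean(codeᵢ) by linearity, independent of the joint
arrangement) are reproduced exactly, whereas odds ratios and p-values
depend on the joint arrangement and only scatter around the published
values.  Passing tests therefore validate the pipeline's arithmetic and
inference machinery, not the study's subject-level data, which were never
deposited.

## Numerical and reporting choices

- Rounding everywhere user-facing is half-away-from-zero (via decimal
  arithmetic, so printed halves round as written): 2 decimals for
  frequencies, 1 for score means, integer for points.
- Reported odds ratios format as `X.XX (L–U)`.
- Simulations are driven by `numpy.random.default_rng(seed)`; a (spec,
  seed) pair determines a cohort bit-for-bit, and pipeline reruns with the
  same seed produce byte-identical bundles.
- Problem sizes in the validation experiments: the 2×2 oracle enumeration
  covers all 810,000 tables with cells 1..30; parameter recovery uses 200
  replicates of n = 20,000; type-I calibration 400 replicates of
  n = 10,000 (rejection fraction checked against the 99% binomial band
  2.2–7.8%); coding-selection consistency 100 replicates of n = 5,000.

## Known limitations

- Wald intervals only; no profile-likelihood or exact intervals, no Firth
  penalization, so very sparse bands yield very wide (or unavailable)
  estimates — surfaced, not smoothed over.
- The published healthy-group mean score (0.8) is inconsistent with the
  healthy genotype margins, which imply 0.73 by linearity; the package
  reports the computed value.
- The published KLF6 standardized weight (0.46/0.43 = 1.06) appears to be
  computed from unrounded coefficients; the integer points are unaffected.
- VCF input is deliberately minimal: biallelic records matched by rsID,
  GT field only; multi-allelic sites and non-diploid calls are errors.
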