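# Methods

## The estimation problem

Type 1 diabetes presenting after age 30 is hard to count: it is a small
minority against the rising background of type 2 diabetes, and the available
biomarkers (islet autoantibodies, C-peptide) have false-positive rates of the
same order as the quantity being measured. `genestrat` implements a
population-level alternative: count it genetically, by stratification and
subtraction, without ever classifying an individual.

The method rests on three assumptions:

1. A polygenic type 1 diabetes risk score (GRS) separates the population such
   that only a small fraction *f* of true type 1 cases score below the
   population median (*f* ≈ 0.04 in reference type 1 cohorts).
2. Type 1 genetic susceptibility does not predispose to type 2 diabetes, so
   the GRS distribution of type 2 cases (and of unaffected individuals)
   matches the general population — in particular, type 2 cases split 50/50
   across the population median.
3. Genetic risk is fixed from birth, so a cross-sectional cohort supports
   survival analysis on the age timescale.

Under these assumptions, splitting the cohort at the median GRS and counting
diabetes cases in each half gives

    n_T1D ≈ n_H − n_L,

the *excess* of cases in the high half, with expectation
(1 − 2f) · n_T1D(true): the fraction *f* of type 1 cases below the median is
lost from the high half and cancels an equal count in the low half.

## The genetic risk score

For individual *i*,

    GRS_i = w_HLA(g_i1, g_i2) + Σ_v d_iv · ln(OR_v)

where `d_iv ∈ [0, 2]` is the effect-allele dosage at additive variant *v*,
`ln(OR_v)` its log odds ratio, and `w_HLA` a 3×3 diplotype weight table
indexed by the hard-call genotypes at two HLA tag SNPs (rs2187668 tagging
DR3, rs7454108 tagging DR4-DQ8). The diplotype term is non-additive because
the DR3/DR4 heterozygote carries more risk than either homozygote. Dosages
are hard-called by nearest-integer rounding (ties to even); dosages more than
0.1 from an integer are flagged. Samples missing any score variant are
excluded by default; mean imputation by 2 × allele frequency is available by
flag.

The published variant list and weights are not reproduced here; the shipped
weight set (`placeholder_weights`) is a synthetic stand-in with plausible
ln-OR magnitudes and a diplotype table obeying the ordering
DR3/DR4-heterozygote > single-haplotype > neither. Every statistical property
of the pipeline is weight-table-agnostic; only the absolute score scale
depends on it.

**Hardy-Weinberg QC.** Candidate additive variants are tested with the 1-df
chi-square comparing observed genotype counts to expectations at the
observed allele frequency; variants with p below `hwe_exclusion_p`
(default 1e-6) are dropped from the score. Monomorphic variants return
chi-square 0 / p 1 (no evidence of departure). An exact Levene–Haldane mid-p
test is provided as a cross-check; at biobank scale and the thresholds used,
the choice is immaterial.

## Stratification and survival

Individuals with scores strictly above (below) the median form the high (low)
group. Ties exactly at the median are alternated deterministically in
sample-id sort order into whichever group is currently smaller, balancing the
halves to within one; the rule is arbitrary but reproducible.

Diabetes-free survival uses the product-limit (Kaplan-Meier) estimator on the
age timescale: events at the self-reported integer age of diagnosis,
censoring at the age of study entry for unaffected individuals, and
administrative censoring at `censor_age` (default 60) for everyone —
diagnoses recorded after that age count as censored non-events. Beyond age
60 the at-risk population thins and the type 2 background overwhelms the
subtraction, so the estimator is not extended there. The group hazard ratio
uses the observed/expected log-rank form, HR = (O_H/E_H)/(O_L/E_L), with a
log-scale normal CI (SE² = 1/E_H + 1/E_L); no proportional-hazards model is
fitted.

## The subtraction estimator

With cases counted at or before the censoring age:

* overall excess: `n_H − n_L`, reported with its share of all cases as a
  percentage;
* per age band (right-closed integer bands, default 0–30 and 31–60, the first
  band including age 0) and per decade: band excesses sum to the overall
  excess exactly;
* cumulative excess by age of diagnosis (one point per year, 1..60);
* per-decade "type 2" counts are total − excess, so the two series always sum
  to the observed totals.

Negative excesses are possible under sampling noise, are flagged, and are
never clamped — clamping would break the conservation identities and bias
the totals.

**CI for the excess share.** The default is a percentile bootstrap over
individuals (2,000 seeded replicates). Because the share depends on the data
only through the category counts (high-case, low-case, non-case),
resampling individuals is implemented as a single multinomial redraw of
those counts per replicate. A Wald alternative (independent-Poisson counts,
delta method) is available (`ci_method="wald"`); the two agree closely at
biobank n and the Wald form is used where many repeated fits are needed.

## Derived characteristics of the latent group

The latent type 1 group is never identified individually; its summaries
follow algebraically. For a continuous characteristic with band group sizes
n_H, n_L and means x̄_H, x̄_L:

    x̄_T1D = (n_H x̄_H − n_L x̄_L) / n_T1D,    n_T1D = n_H − n_L.

SDs are recovered by the same subtraction applied to second moments,
E[X²] = σ² + x̄² in the *population* (divide-by-n) convention, under which
the identity is exact for any true decomposition of the high group into the
low group plus a latent group (the constructive oracle in the test suite).
Inputs/outputs in the sample convention are supported through a `ddof`
argument. BMI is the exception: its pooled distribution is bimodal, so the
subtracted second moment is unstable and the type 2 group's SD is borrowed
instead (`borrow_t2d_sd`). A negative reconstructed variance raises an error
naming the inputs — it signals inconsistent summaries or noise-dominated
subtraction, not a recoverable condition.

Categorical characteristics are subtracted per category as count excesses,
with derived proportion excess/n_T1D. The type 2 comparison group is the low
half's cases weighted to the full type 2 count (total − excess, which equals
exactly twice the low count) — the low half *is* the type 2 distribution
under assumption 2.

**Comparisons.** Continuous: Welch two-sample t tests from summary
statistics (the derived SDs differ between groups by construction, so equal
variances are not assumed). Categorical: 2×2 chi-square without continuity
correction (a continuity-corrected variant is available by flag); tables
with a negative derived cell or a zero marginal are reported missing with a
warning rather than tested. p-values are Bonferroni-adjusted over the seven
tested characteristics (age at entry, age at diagnosis, sex, BMI, insulin
within 1 year, insulin at entry, ketoacidosis admission), adjusted
p = min(1, 7 × raw).

CIs for derived means use a percentile bootstrap over individual case
records within each half (vectorised as multinomial resampling weights);
derived proportions bootstrap the two category counts binomially. The delta
method variance (n_H s_H² + n_L s_L²)/n_T1D² is the fast alternative.

## The synthetic cohort generator

Real biobank data is access-restricted, so the generator emulates the fields
and the statistical structure the method assumes, with truth labels for
validation. Defaults (the study conditions; all overridable):

| parameter | default | rationale |
|---|---|---|
| n_individuals | 380,000 | biobank scale |
| t1d_prevalence | 0.0034 | diagnosed type 1 by entry |
| t2d_prevalence | 0.031 | diagnosed type 2 by entry (total ≈ 3.5%) |
| frac_t1d_below_median | 0.04 | reference-cohort score overlap |
| T1D onset | 60% U{0..30}, 40% U{31..60} | spread across six decades |
| T2D onset | exp-rising on (20, 60], 5% by age 30 | steep rise with age |
| enrolment age | U{40..69} | middle-aged volunteer cohort |
| BMI (T1D / T2D / none) | 27.4/4.5, 32.4/6.0, 27.0/4.5 | class-conditional normals |
| insulin ≤1yr (T1D young / old / T2D) | 0.97 / 0.89 / 0.055 | rapid insulin dependence in T1D |
| insulin at entry (T1D young / old / T2D) | 0.99 / 1.0 / 0.16 | near-universal in T1D |
| DKA admission (T1D / T2D) | 0.10 / 0.003 | absolute insulin deficiency marker |
| male fraction (T1D / T2D / none) | 0.59 / 0.66 / 0.5 | modest male excess in diabetes |

Genotypes are drawn independently per variant as Binomial(2, p) — i.e. under
Hardy-Weinberg equilibrium — at fixed allele frequencies. The population
median score is computed from this initial draw; each type 1 individual's
genotype vector is then rejection-resampled until its score lands on its
intended side of that median (below with probability
`frac_t1d_below_median`). This directly parameterises the one quantity the
method depends on, without inventing per-variant effect sizes. Type 2 and
unaffected individuals keep their initial genotypes, making their score
distribution identical to the population by construction (the structural
null). Onset ages are redrawn until no later than enrolment.

What the generator does **not** emulate, and hence what passing tests do not
demonstrate about real data: linkage disequilibrium between score variants;
genuine per-variant genotype–disease effect sizes (the score–disease link is
imposed at the score level); birth-cohort trends in incidence; volunteer
selection bias; self-report error; relatedness and ancestry structure.

One structural consequence worth knowing: because diagnosis must precede
enrolment and enrolment is uniform on 40–69, late onsets are truncated. The
realized share of type 1 onsets in the 31–60 band is ~30% (against the 40%
nominal mixture weight), realized type 2 onsets by age 30 are ~12% (against
the 5% nominal), and per-decade type 2 counts peak in the 41–50 decade
rather than rising to 60. Estimator-validation tests therefore compare
against the cohort's *realized* truth labels, not the nominal mixture
weights.

## Numerical and scale choices

* Scores are exact floating-point affine functions of dosage; no tolerance
  is involved beyond machine precision.
* Product-limit curves use cumulative products over distinct times; tied
  integer event ages are handled by the standard d_i/n_i factor.
* All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); pipeline reruns are byte-identical.
* Validation test scales: full-scale recovery runs at n = 380,000 (a few
  seconds per cohort); null calibration at 100 seeds × n = 100,000 with the
  Wald CI; reduced-scale hazard-ratio calibration at 30 seeds × n = 20,000.
  These sizes give Monte-Carlo SEs comfortably inside the 3-SE acceptance
  bands while keeping the suite quick.
* Floats in output CSVs carry 6 significant digits.

## Known limitations

* The estimator is aggregate-only: it cannot classify individuals, and the
  package deliberately exposes no per-individual type 1 probability.
* The subtraction is noise-dominated when n_T1D is small relative to
  √(type 2 cases); derived proportions can then exceed 100% or go negative.
  They are reported as computed, with warnings.
* Above the censoring age the method is uninterpretable and not offered.
* The placeholder weight set means absolute score values (e.g. the median
  cutoff) are not comparable to published cutoffs.
* The score and the method's validation apply to populations where the GRS
  has been validated; the generator models a single homogeneous ancestry.
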