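# Methods

This note documents the models and numerical choices behind `demrisk`:
what each stage assumes, which knobs matter, and what the synthetic
data can and cannot tell you about real cohorts.

## Risk scores as declarative weight tables

Each index is an additive point score over categorical factor levels.
The entire computational content of an index lives in a YAML table
(`src/demrisk/data/weights/`): one entry per (factor, level) cell with
optional sex and baseline-age-band conditions, a `demographic` flag on
age/sex/education entries, and the verbatim source cell in
`source_quote`. The scorer is a pure sum over matched entries, kept in
integer centi-points (points × 100; every published weight has at most
two decimals) so totals are exact and independent of summation order.

Transcription notes worth knowing:

- A few cells in the available reproduction of the source weight table
  are typographically damaged (the cognitive-activity rows). They are
  resolved as CogDrisk medium/high = −4/−5 and LIBRA high = −3.2,
  which reconstructs the printed observed score minima exactly
  (CogDrisk −8.25 = −3 − 0.25 − 5; LIBRA −5.9 = −1 − 3.2 − 1.7). Any
  cell can be overridden at load time
  (`load_weight_table(..., overrides={(factor, level, sex): points})`)
  without editing the files.
- The ANU-ADRI education and social-activity gradients and the LIBRA2
  social-contact weight are transcribed exactly as printed even though
  their direction looks inverted relative to the indices' original
  publications; correcting them silently would make the implementation
  untraceable against its source. Use the override mechanism to flip
  them if desired.
- Pesticide exposure (ANU-ADRI) and chronic kidney disease (LIBRA) are
  omitted entirely, matching the analysis the tables come from.
- LIBRA and LIBRA2 were published without demographic items; their
  parenthesized "borrowed" age/education entries carry
  `borrowed: true` and participate only in the with-demographics
  variant.
- Ex-smokers score the ANU-ADRI ex-smoker weight; every other index
  groups them with never-smokers (handled in the scorer, not the
  tables).
- CAIDE's physical activity is its own binary factor: *active* means at
  least two sessions and at least 60 minutes (30 min × 2) of
  moderate-to-vigorous activity per week. The three-level
  minutes-per-week variable (<30 / 30–149 / ≥150) serves the other
  indices.
- Complete-case scoring is the default: an index value is missing when
  any covered factor is missing. Permissive mode (missing factors
  contribute 0, listed in the output) exists for exploration and is
  clearly flagged.

`theoretical_range` computes attainable score bounds by per-factor
extreme selection — valid because the score is additively separable —
scanning both sexes to resolve sex-conditioned cells; it is verified
against brute-force enumeration on reduced tables in the test suite.

## Harmonization

Raw measurements map to factor levels by the published thresholds: BMI
bands <18.5 / 18.5–24.99 / 25–29.99 / ≥30 with boundary values going to
the upper band; alcohol none / 1–14 / ≥14 units per week, where the
overlapping printed boundary at exactly 14 is assigned to *high* (the
more specific risk condition) and logged; HADS-D ≥ 8 codes depression;
total cholesterol ≥ 6.5 mmol/L; non-fasting glucose ≥ 9 mmol/L or a
self-reported diagnosis codes diabetes; hypertension uses the mean of
the 2nd and 3rd systolic readings (mean of whatever is available when
one is missing, logged) at ≥ 140 mmHg; education bands <8 / 8–11 / >11
years (an 8–12/>12 variant is a config switch).

Precedence is: survey first; a positive earlier-wave report carries
forward (hearing always; stroke only when the baseline survey is
missing); 3-digit ICD-10 registry codes dated 2007–2009 fill in only
when the survey value is missing (depression F32–F33, diabetes
E10–E14, hypertension I10/I15, heart disease I11/I20–I25/I50–I51,
stroke I60–I69, TBI S06–S07/S09). Absence of a registry code is never
treated as evidence of absence, so survey-missing/registry-negative
stays missing. Survey wins conflicts, which are logged. Every factor
carries a provenance tag (survey / earlier_wave / registry / derived /
missing).

Cognitive and social activity are cohort-relative composites: each
component is z-scored on the analytic cohort (equal weights — the
source analysis does not state its weighting), summed, and cut at
empirical tertiles/quartiles. The quantile engine is rank-based
(groups cut at positions j·n/k, tie groups assigned to the lower
group), chosen because it is deterministic, rank-only and stable under
monotone transforms; when values are distinct, group sizes differ by at
most one.

## Synthetic cohorts

The generator draws a latent multivariate normal over age plus twenty
factor dimensions and thresholds each dimension at the quantiles
implied by the configured marginal prevalences (a Gaussian copula).
The latent-normal dependence family was chosen deliberately: it is the
same family the imputation stage assumes, so generator and imputer are
aligned. The default dependence structure is a one-factor model,
corr(i,j) = λᵢλⱼ (always positive semidefinite), with loadings that
read as age-related frailty (age 0.7, hearing 0.5, heart disease 0.4,
hypertension 0.35, physical activity −0.3, cognitive activity −0.3,
…). An explicit full correlation matrix can be supplied instead; it is
validated (symmetry, unit diagonal, PSD) and rejected naming the
offending eigenvalue.

Default conditions are transcribed from the analytic-sample column of
the source cohort's descriptive table: 52.8 % women, baseline age
66.6 ± 5.8 years, the per-factor prevalences in
`data/cohort_defaults.yaml`, and a dementia outcome targeting 10.8 %
marginal prevalence (AD fraction 0.583 of dementia). The outcome is
Bernoulli from a logistic model on baseline age (default log-odds
0.148/year ≈ OR 1.16), ordered education (−0.478/level ≈ OR 0.62) and
a configurable subset of factor levels; the intercept is calibrated by
root-finding so the realized cohort hits the target prevalence.
Cognitive/social activity are assigned by within-sample latent rank
(they are cohort-relative constructs, so they carry no marginal
prevalence).

Raw fields are back-filled inside the assigned category's numeric
interval (uniformly, with a small margin and physiologic truncation,
e.g. systolic readings in 92–138 vs 140–220 mmHg recorded to the
nearest 2 mmHg; weight derived from the already-rounded height so
recording precision cannot cross a BMI cut point). Composite
components are deterministic monotone transforms of the factor's
latent value with at least one strictly increasing continuous item, so
the harmonizer's z-sum composite preserves the latent ranking exactly.
This guarantees the identity *harmonize ∘ generate = truth* for every
factor of every record — the backbone of the test suite — at the cost
of realism: within-category measurement noise, inconsistent
questionnaire answers, and discordant composite items do not occur.
Passing tests therefore certify the pipeline's logic, not its
robustness to messy real-world measurement.

MAR missingness blanks raw variable groups with per-group logistic
probabilities in age, sex and education only (the imputation
predictors), shaped so participants with missing data are older, more
often female and less educated. Outcome and id are never blanked.
Registry codes are emitted for 25 % of condition-positive participants
so the registry fallback path is exercised.

## Evaluation

Index scores are z-standardized (mean 0, SD 1, n−1 denominator) before
entering a logistic model, so coefficients are per-SD and invariant to
each index's arbitrary scale. Fits are maximum likelihood
(statsmodels), CIs are Wald on the log-odds scale (the source analysis
does not state its CI method), pseudo-R² is McFadden's 1 − ℓ/ℓ₀.
Quasi-complete separation is flagged and refit with a light L2
penalty. The reference model is age plus education entered as a single
ordered numeric covariate (a dummy-coded switch exists).

AUCs are midrank Mann–Whitney statistics; their joint covariance comes
from the DeLong placement-value decomposition. The comparison
procedure is gated: a global chi-square contrast test across all
curves (k−1 df, pseudo-inverse quadratic form so identical curves
degrade to p = 1) must reach p ≤ 0.05 before any pairwise z-tests are
reported; contrasts against the demographics reference are reported
regardless, starred at 0.05 / 0.005 / 0.001. By default the reference
curve is included among the globally compared curves (switchable).
AUC labels use the conventional bands (0.5–0.6 fail … 0.8–0.9 good).

Stratified analyses (sex; baseline age < 65 vs ≥ 65, matching the
table labels of the source analysis rather than its prose "≤65 vs >65",
with the cut configurable; APOE4 carriership) refit the index models
and the demographics reference within each stratum, for all-cause
dementia only. Standardization parameters are estimated once on the
full analytic sample and reused in strata so per-SD odds ratios remain
comparable across strata (a per-stratum alternative is a flag); the
source analysis is silent on this point. AD analyses drop non-AD
dementia cases (coded missing) before fitting.

## Multiple imputation

Harmonized factor levels are coded numerically and modelled jointly
with the always-complete predictors (age, sex, education, dementia
status — the outcome is a predictor but is never imputed) as
multivariate normal. Draws come from a data-augmentation Gibbs sampler
(statsmodels `BayesGaussMI`): 200 burn-in sweeps, thinning interval 10
between the m retained datasets (defaults; recorded in output
metadata). Imputed cells are rounded to the nearest legal category
code — adaptive rounding was considered and rejected for determinism
and simplicity. Observed cells are never altered; runs are
deterministic per seed. Factors are imputed and the indices then
*rescored* (imputing the scores directly is the alternative behind a
flag, not the default). m defaults to 100; tests run at m = 2–20 with
the scale-down flagged in their output.

Rubin pooling: q̄ = mean estimate, b = between-imputation variance
(ddof 1, snapped to exactly zero when it is pure floating-point
roundoff so the no-missingness limit is exact), total variance
T = ū + (1 + 1/m)b, RVI = (1 + 1/m)b/ū, Barnard–Rubin small-sample
degrees of freedom, FMI = (RVI + 2/(ν+3))/(1 + RVI). The model-level
F statistic is the squared pooled Wald ratio on (1, ν) df.

Index-specific available-case refits rerun each index on all
participants complete for that index regardless of the others, with
the demographics model on the union sample.

## Validation design choices

Two validation experiments deserve explanation because their designs
are themselves choices:

- **MAR recovery.** Missingness driven only by the outcome would not
  bias logistic slopes (the case-control property), so the recovery
  experiment links missingness to both age and outcome while the
  analysis model omits age — the textbook situation where complete-case
  slopes are biased and conditioning the imputation on age and outcome
  repairs them. Pooled estimates beat complete case on mean absolute
  deviation from the full-data estimate over 100 replicates.
- **Planted AUC ordering.** Outcome effects are planted on
  index-distinctive factors (stroke and loneliness → CogDrisk; hearing
  → LIBRA2; Mediterranean diet and protective moderate alcohol →
  LIBRA; APOE4 → CAIDE; demographic effects zeroed) with magnitudes
  chosen so the implied discrimination ordering CogDrisk > LIBRA2 >
  LIBRA > CAIDE > ANU-ADRI has AUC gaps of roughly 0.02 at the n =
  10,000 per-run scale. The pipeline recovers the full five-way
  ordering in ≥ 95 % of seeded runs.

## Problem sizes

Simulation-based checks run at sizes chosen to keep the whole suite in
a few minutes on one CPU while leaving comfortable statistical margins:
DeLong null calibration at 1,000 replicates of n = 400; bootstrap
variance cross-check at 2,000 resamples of n = 500; logistic coverage
at 500 replicates of n = 5,000; the binormal AUC limit at 50,000
observations; imputation recovery at 100 replicates of n = 2,000 with
m = 20; determinism and the acceptance run at the study scale
n ≈ 5,247 with m = 100.

## Known limitations

- The synthetic cohort has no measurement error within categories, no
  longitudinal structure (the follow-up age is baseline plus a uniform
  gap; no time-to-event, no competing mortality), and no survey
  non-response patterns beyond the configured MAR model.
- Genotype simulation stops at the ε4 allele count; no linkage to
  other loci.
- Registry codes are emitted only for true positives, so the
  harmonizer's registry path is exercised but false-positive codes are
  not modelled.
- The weight tables reproduce one printed source, including its
  apparent oddities; they are not re-derived from the indices' original
  publications.
- Calibration metrics (Brier score, calibration slope), external-
  cohort validation, inverse-probability weighting and competing-risk
  extensions are out of scope.
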