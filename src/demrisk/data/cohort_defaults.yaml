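# Default synthetic-cohort conditions: marginal factor prevalences
# transcribed from the analytic-sample ("N included") column of the source
# cohort's descriptive table, demographic moments from the same table, and
# an outcome model calibrated to the observed 10.8 % dementia prevalence.
# Cognitive and social activity are cohort-relative rank constructs
# (tertiles / quartiles) and therefore carry no marginal prevalences.
demographics:
  age_mean: 66.6
  age_sd: 5.8
  age_range: [45.0, 100.0]
  female_fraction: 0.528
  followup_gap_years: [9.5, 11.5]

factor_prevalences:
  education_level: {low: 0.001, medium: 0.643, high: 0.356}
  alcohol: {none: 0.748, low_moderate: 0.247, high: 0.005}
  apoe_carrier: {non_carrier: 0.733, carrier: 0.267}
  bmi: {underweight: 0.004, normal: 0.242, overweight: 0.507, obese: 0.247}
  heart_disease: {"no": 0.834, "yes": 0.166}
  depression: {"no": 0.902, "yes": 0.098}
  diabetes: {"no": 0.916, "yes": 0.084}
  fish_intake: {"0-0.25": 0.230, "0.26-2": 0.686, "2.1-4": 0.061, ">4.1": 0.023}
  mediterranean_diet: {unhealthy: 0.422, healthy: 0.578}
  hearing_impairment: {"no": 0.549, "yes": 0.451}
  hypercholesterolemia: {"no": 0.749, "yes": 0.251}
  hypertension: {"no": 0.531, "yes": 0.469}
  physical_activity: {inactive: 0.180, medium: 0.008, high: 0.812}
  tbi: {"no": 0.935, "yes": 0.065}
  sleep_disturbance: {"no": 0.684, "yes": 0.316}
  smoking: {never: 0.422, former: 0.424, current: 0.154}
  lonely: {"no": 0.820, "yes": 0.180}
  stroke: {"no": 0.961, "yes": 0.039}

# One-factor latent loadings: corr(i, j) = loading_i * loading_j, which is
# always positive semidefinite. The shared latent reads as age-related
# frailty; negative loadings mark factors that decline with it.
latent_loadings:
  age: 0.70
  education_level: -0.25
  alcohol: -0.10
  apoe_carrier: 0.0
  bmi: 0.10
  cognitive_activity: -0.30
  heart_disease: 0.40
  depression: 0.10
  diabetes: 0.25
  fish_intake: 0.10
  mediterranean_diet: 0.05
  hearing_impairment: 0.50
  hypercholesterolemia: 0.15
  hypertension: 0.35
  physical_activity: -0.30
  tbi: 0.05
  sleep_disturbance: 0.15
  smoking: -0.10
  social_activity: -0.15
  lonely: 0.15
  stroke: 0.25

outcome_model:
  target_prevalence: 0.108
  ad_fraction_of_dementia: 0.583     # 6.3 % AD of 10.8 % dementia overall
  amci_fraction_of_nondementia: 0.12
  namci_fraction_of_nondementia: 0.08
  age_per_year: 0.148                # log-odds; exp = 1.16 per year
  education_per_level: -0.478        # log-odds; exp = 0.62 per level
  factor_effects:
    apoe_carrier: {carrier: 0.70}
    diabetes: {"yes": 0.35}
    stroke: {"yes": 0.50}
    depression: {"yes": 0.30}
    hypertension: {"yes": 0.15}
    hearing_impairment: {"yes": 0.30}
    smoking: {current: 0.25}
    physical_activity: {inactive: 0.25}
    lonely: {"yes": 0.20}
    cognitive_activity: {low: 0.25}

# MAR missingness: per-variable-group logistic models on baseline age
# (centered at 67), sex (female = 1) and education level (0/1/2), shaped
# so that participants with missing data are older, more often female,
# and less educated.
missingness_model:
  blood_pressure: {intercept: -2.5, age_per_year: 0.04, female: 0.15, education_per_level: -0.20}
  cholesterol: {intercept: -2.6, age_per_year: 0.04, female: 0.15, education_per_level: -0.20}
  hads: {intercept: -2.7, age_per_year: 0.05, female: 0.10, education_per_level: -0.25}
  mvpa: {intercept: -2.3, age_per_year: 0.05, female: 0.15, education_per_level: -0.25}
  diet: {intercept: -2.8, age_per_year: 0.04, female: 0.10, education_per_level: -0.20}
  alcohol: {intercept: -2.9, age_per_year: 0.04, female: 0.15, education_per_level: -0.20}

registry_report_rate: 0.25
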