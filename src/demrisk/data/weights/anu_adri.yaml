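# ANU-ADRI point weights, transcribed cell-by-cell from the published
# descriptive weight table. Pesticide exposure is omitted (no data source).
# `source_quote` holds the verbatim printed cell; ambiguous cells can be
# overridden per-cell at load time (see demrisk.weights.load_weight_table).
index: ANU-ADRI
version: 1
source: published index weight table transcription
entries:
  # -- demographic: age, sex-specific 5-year bands (baseline age) --
  - {factor: age, level: "<65", sex: male, age_min: null, age_max: 65, points: 0, demographic: true, source_quote: "0"}
  - {factor: age, level: "65-69", sex: male, age_min: 65, age_max: 70, points: 1, demographic: true, source_quote: "1"}
  - {factor: age, level: "70-74", sex: male, age_min: 70, age_max: 75, points: 12, demographic: true, source_quote: "12"}
  - {factor: age, level: "75-79", sex: male, age_min: 75, age_max: 80, points: 18, demographic: true, source_quote: "18"}
  - {factor: age, level: "80-84", sex: male, age_min: 80, age_max: 85, points: 26, demographic: true, source_quote: "26"}
  - {factor: age, level: "85-89", sex: male, age_min: 85, age_max: 90, points: 33, demographic: true, source_quote: "33"}
  - {factor: age, level: ">=90", sex: male, age_min: 90, age_max: null, points: 38, demographic: true, source_quote: "38"}
  - {factor: age, level: "<65", sex: female, age_min: null, age_max: 65, points: 0, demographic: true, source_quote: "0"}
  - {factor: age, level: "65-69", sex: female, age_min: 65, age_max: 70, points: 5, demographic: true, source_quote: "5"}
  - {factor: age, level: "70-74", sex: female, age_min: 70, age_max: 75, points: 14, demographic: true, source_quote: "14"}
  - {factor: age, level: "75-79", sex: female, age_min: 75, age_max: 80, points: 21, demographic: true, source_quote: "21"}
  - {factor: age, level: "80-84", sex: female, age_min: 80, age_max: 85, points: 29, demographic: true, source_quote: "29"}
  - {factor: age, level: "85-89", sex: female, age_min: 85, age_max: 90, points: 35, demographic: true, source_quote: "35"}
  - {factor: age, level: ">=90", sex: female, age_min: 90, age_max: null, points: 41, demographic: true, source_quote: "41"}
  # -- demographic: education --
  - {factor: education_level, level: low, points: 0, demographic: true, source_quote: "0"}
  - {factor: education_level, level: medium, points: 3, demographic: true, source_quote: "3"}
  - {factor: education_level, level: high, points: 6, demographic: true, source_quote: "6"}
  # -- alcohol --
  - {factor: alcohol, level: none, points: 0, source_quote: "0"}
  - {factor: alcohol, level: low_moderate, points: -3, source_quote: "-3"}
  - {factor: alcohol, level: high, points: 0, source_quote: "0"}
  # -- BMI (underweight not scored by this index; printed as a dash) --
  - {factor: bmi, level: underweight, points: 0, source_quote: "-"}
  - {factor: bmi, level: normal, points: 0, source_quote: "0"}
  - {factor: bmi, level: overweight, points: 2, source_quote: "2"}
  - {factor: bmi, level: obese, points: 5, source_quote: "5"}
  # -- cognitive activity tertile --
  - {factor: cognitive_activity, level: low, points: 0, source_quote: "0"}
  - {factor: cognitive_activity, level: medium, points: -6, source_quote: "-6"}
  - {factor: cognitive_activity, level: high, points: -7, source_quote: "-7"}
  # -- depression --
  - {factor: depression, level: "no", points: 0, source_quote: "0"}
  - {factor: depression, level: "yes", points: 2, source_quote: "2"}
  # -- diabetes --
  - {factor: diabetes, level: "no", points: 0, source_quote: "0"}
  - {factor: diabetes, level: "yes", points: 3, source_quote: "3"}
  # -- fish intake (servings/week bands) --
  - {factor: fish_intake, level: "0-0.25", points: 0, source_quote: "0"}
  - {factor: fish_intake, level: "0.26-2", points: -3, source_quote: "-3"}
  - {factor: fish_intake, level: "2.1-4", points: -4, source_quote: "-4"}
  - {factor: fish_intake, level: ">4.1", points: -5, source_quote: "-5"}
  # -- hypercholesterolemia --
  - {factor: hypercholesterolemia, level: "no", points: 0, source_quote: "0"}
  - {factor: hypercholesterolemia, level: "yes", points: 3, source_quote: "3"}
  # -- physical activity (3-level) --
  - {factor: physical_activity, level: inactive, points: 0, source_quote: "0"}
  - {factor: physical_activity, level: medium, points: -2, source_quote: "-2"}
  - {factor: physical_activity, level: high, points: -3, source_quote: "-3"}
  # -- traumatic brain injury --
  - {factor: tbi, level: "no", points: 0, source_quote: "0"}
  - {factor: tbi, level: "yes", points: 4, source_quote: "4"}
  # -- smoking (this index scores ex-smokers separately) --
  - {factor: smoking, level: never, points: 0, source_quote: "0"}
  - {factor: smoking, level: former, points: 1, source_quote: "1"}
  - {factor: smoking, level: current, points: 4, source_quote: "4"}
  # -- social activity quartile --
  - {factor: social_activity, level: q1, points: 0, source_quote: "0"}
  - {factor: social_activity, level: q2, points: 1, source_quote: "1"}
  - {factor: social_activity, level: q3, points: 4, source_quote: "4"}
  - {factor: social_activity, level: q4, points: 6, source_quote: "6"}
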