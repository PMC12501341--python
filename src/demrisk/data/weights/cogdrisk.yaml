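# CogDrisk point weights. Diabetes is scored sex-specifically. The
# cognitive-activity cells are typographically damaged in the available
# reproduction of the weight table ("-6--400", "-7--5-3.20"); they are
# resolved as medium = -4, high = -5, which reconstructs the printed
# observed score minimum exactly (-8.25 = -3 physical activity
# - 0.25 fish - 5 cognitive activity). Override per-cell if a cleaner
# source becomes available.
index: CogDrisk
version: 1
source: published index weight table transcription
entries:
  - {factor: age, level: "<65", sex: male, age_min: null, age_max: 65, points: 0, demographic: true, source_quote: "0"}
  - {factor: age, level: "65-69", sex: male, age_min: 65, age_max: 70, points: 6, demographic: true, source_quote: "6"}
  - {factor: age, level: "70-74", sex: male, age_min: 70, age_max: 75, points: 8, demographic: true, source_quote: "8"}
  - {factor: age, level: "75-79", sex: male, age_min: 75, age_max: 80, points: 13, demographic: true, source_quote: "13"}
  - {factor: age, level: "80-84", sex: male, age_min: 80, age_max: 85, points: 17, demographic: true, source_quote: "17"}
  - {factor: age, level: "85-89", sex: male, age_min: 85, age_max: 90, points: 20, demographic: true, source_quote: "20"}
  - {factor: age, level: ">=90", sex: male, age_min: 90, age_max: null, points: 22, demographic: true, source_quote: "22"}
  - {factor: age, level: "<65", sex: female, age_min: null, age_max: 65, points: 0, demographic: true, source_quote: "0"}
  - {factor: age, level: "65-69", sex: female, age_min: 65, age_max: 70, points: 4, demographic: true, source_quote: "4"}
  - {factor: age, level: "70-74", sex: female, age_min: 70, age_max: 75, points: 7, demographic: true, source_quote: "7"}
  - {factor: age, level: "75-79", sex: female, age_min: 75, age_max: 80, points: 11, demographic: true, source_quote: "11"}
  - {factor: age, level: "80-84", sex: female, age_min: 80, age_max: 85, points: 15, demographic: true, source_quote: "15"}
  - {factor: age, level: "85-89", sex: female, age_min: 85, age_max: 90, points: 19, demographic: true, source_quote: "19"}
  - {factor: age, level: ">=90", sex: female, age_min: 90, age_max: null, points: 23, demographic: true, source_quote: "23"}
  - {factor: education_level, level: low, points: 4, demographic: true, source_quote: "4"}
  - {factor: education_level, level: medium, points: 2, demographic: true, source_quote: "2"}
  - {factor: education_level, level: high, points: 0, demographic: true, source_quote: "0"}
  - {factor: bmi, level: underweight, points: 2, source_quote: "2"}
  - {factor: bmi, level: normal, points: 0, source_quote: "0"}
  - {factor: bmi, level: overweight, points: 1, source_quote: "1"}
  - {factor: bmi, level: obese, points: 3, source_quote: "3"}
  - {factor: cognitive_activity, level: low, points: 0, source_quote: "0"}
  - {factor: cognitive_activity, level: medium, points: -4, source_quote: "-6--400 (damaged cell, read as -4)"}
  - {factor: cognitive_activity, level: high, points: -5, source_quote: "-7--5-3.20 (damaged cell, read as -5)"}
  - {factor: heart_disease, level: "no", points: 0, source_quote: "0"}
  - {factor: heart_disease, level: "yes", points: 2, source_quote: "2"}
  - {factor: depression, level: "no", points: 0, source_quote: "0"}
  - {factor: depression, level: "yes", points: 3, source_quote: "3"}
  - {factor: diabetes, level: "no", sex: male, points: 0, source_quote: "0 (M)"}
  - {factor: diabetes, level: "no", sex: female, points: 0, source_quote: "0 (F)"}
  - {factor: diabetes, level: "yes", sex: male, points: 2, source_quote: "2 (M)"}
  - {factor: diabetes, level: "yes", sex: female, points: 3, source_quote: "3 (F)"}
  - {factor: fish_intake, level: "0-0.25", points: 0, source_quote: "0"}
  - {factor: fish_intake, level: "0.26-2", points: -0.25, source_quote: "-0.25"}
  - {factor: fish_intake, level: "2.1-4", points: -0.25, source_quote: "-0.25"}
  - {factor: fish_intake, level: ">4.1", points: -0.25, source_quote: "-0.25"}
  - {factor: hypercholesterolemia, level: "no", points: 0, source_quote: "0"}
  - {factor: hypercholesterolemia, level: "yes", points: 3, source_quote: "3"}
  - {factor: hypertension, level: "no", points: 0, source_quote: "0"}
  - {factor: hypertension, level: "yes", points: 1, source_quote: "1"}
  - {factor: physical_activity, level: inactive, points: 0, source_quote: "0"}
  - {factor: physical_activity, level: medium, points: -3, source_quote: "-3"}
  - {factor: physical_activity, level: high, points: -3, source_quote: "-3"}
  - {factor: tbi, level: "no", points: 0, source_quote: "0"}
  - {factor: tbi, level: "yes", points: 2, source_quote: "2"}
  - {factor: sleep_disturbance, level: "no", points: 0, source_quote: "0"}
  - {factor: sleep_disturbance, level: "yes", points: 2, source_quote: "2"}
  - {factor: smoking, level: never, points: 0, source_quote: "0"}
  - {factor: smoking, level: current, points: 1, source_quote: "1"}
  - {factor: lonely, level: "no", points: 0, source_quote: "0"}
  - {factor: lonely, level: "yes", points: 2, source_quote: "2"}
  - {factor: stroke, level: "no", points: 0, source_quote: "0"}
  - {factor: stroke, level: "yes", points: 2, source_quote: "2"}
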