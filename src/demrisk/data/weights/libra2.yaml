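# LIBRA2 point weights (updated LIBRA with sleep, social contact, and
# hearing items; rescaled all-nonnegative weights). Borrowed demographic
# entries as in LIBRA. The social-activity gradient is transcribed exactly
# as printed (6.5 on the "Highest" quartile row); see package notes on
# gradients that appear inverted relative to the original publications.
index: LIBRA2
version: 1
source: published index weight table transcription
entries:
  - {factor: age, level: "<65", sex: male, age_min: null, age_max: 65, points: 0, demographic: true, borrowed: true, source_quote: "(0)"}
  - {factor: age, level: "65-69", sex: male, age_min: 65, age_max: 70, points: 0.4, demographic: true, borrowed: true, source_quote: "(0.4)"}
  - {factor: age, level: "70-74", sex: male, age_min: 70, age_max: 75, points: 5.2, demographic: true, borrowed: true, source_quote: "(5.2)"}
  - {factor: age, level: "75-79", sex: male, age_min: 75, age_max: 80, points: 6.8, demographic: true, borrowed: true, source_quote: "(6.8)"}
  - {factor: age, level: "80-84", sex: male, age_min: 80, age_max: 85, points: 11.2, demographic: true, borrowed: true, source_quote: "(11.2)"}
  - {factor: age, level: "85-89", sex: male, age_min: 85, age_max: 90, points: 14.1, demographic: true, borrowed: true, source_quote: "(14.1)"}
  - {factor: age, level: ">=90", sex: male, age_min: 90, age_max: null, points: 16.4, demographic: true, borrowed: true, source_quote: "(16.4)"}
  - {factor: age, level: "<65", sex: female, age_min: null, age_max: 65, points: 0, demographic: true, borrowed: true, source_quote: "(0)"}
  - {factor: age, level: "65-69", sex: female, age_min: 65, age_max: 70, points: 2.1, demographic: true, borrowed: true, source_quote: "(2.1)"}
  - {factor: age, level: "70-74", sex: female, age_min: 70, age_max: 75, points: 6.2, demographic: true, borrowed: true, source_quote: "(6.2)"}
  - {factor: age, level: "75-79", sex: female, age_min: 75, age_max: 80, points: 9.2, demographic: true, borrowed: true, source_quote: "(9.2)"}
  - {factor: age, level: "80-84", sex: female, age_min: 80, age_max: 85, points: 12.4, demographic: true, borrowed: true, source_quote: "(12.4)"}
  - {factor: age, level: "85-89", sex: female, age_min: 85, age_max: 90, points: 15.3, demographic: true, borrowed: true, source_quote: "(15.3)"}
  - {factor: age, level: ">=90", sex: female, age_min: 90, age_max: null, points: 17.6, demographic: true, borrowed: true, source_quote: "(17.6)"}
  - {factor: education_level, level: low, points: 2.7, demographic: true, borrowed: true, source_quote: "(2.7)"}
  - {factor: education_level, level: medium, points: 1.4, demographic: true, borrowed: true, source_quote: "(1.4)"}
  - {factor: education_level, level: high, points: 0, demographic: true, borrowed: true, source_quote: "(0)"}
  - {factor: alcohol, level: none, points: 0, source_quote: "0"}
  - {factor: alcohol, level: low_moderate, points: 0, source_quote: "0"}
  - {factor: alcohol, level: high, points: 3.1, source_quote: "3.1"}
  - {factor: bmi, level: underweight, points: 0, source_quote: "-"}
  - {factor: bmi, level: normal, points: 0, source_quote: "0"}
  - {factor: bmi, level: overweight, points: 0, source_quote: "0"}
  - {factor: bmi, level: obese, points: 7, source_quote: "7"}
  - {factor: cognitive_activity, level: low, points: 9.4, source_quote: "9.4"}
  - {factor: cognitive_activity, level: medium, points: 0, source_quote: "-6--400 (damaged cell, read as 0)"}
  - {factor: cognitive_activity, level: high, points: 0, source_quote: "-7--5-3.20 (damaged cell, read as 0)"}
  - {factor: heart_disease, level: "no", points: 0, source_quote: "-"}
  - {factor: heart_disease, level: "yes", points: 8.3, source_quote: "8.3"}
  - {factor: depression, level: "no", points: 0, source_quote: "0"}
  - {factor: depression, level: "yes", points: 13, source_quote: "13"}
  - {factor: diabetes, level: "no", points: 0, source_quote: "0"}
  - {factor: diabetes, level: "yes", points: 6.8, source_quote: "6.8"}
  - {factor: mediterranean_diet, level: healthy, points: 0, source_quote: "0"}
  - {factor: mediterranean_diet, level: unhealthy, points: 3.8, source_quote: "3.8"}
  - {factor: hearing_impairment, level: "no", points: 0, source_quote: "0"}
  - {factor: hearing_impairment, level: "yes", points: 7.6, source_quote: "7.6"}
  - {factor: hypercholesterolemia, level: "no", points: 0, source_quote: "0"}
  - {factor: hypercholesterolemia, level: "yes", points: 8.2, source_quote: "8.2"}
  - {factor: hypertension, level: "no", points: 0, source_quote: "0"}
  - {factor: hypertension, level: "yes", points: 3.5, source_quote: "3.5"}
  - {factor: physical_activity, level: inactive, points: 6, source_quote: "6"}
  - {factor: physical_activity, level: medium, points: 0, source_quote: "0"}
  - {factor: physical_activity, level: high, points: 0, source_quote: "0"}
  - {factor: sleep_disturbance, level: "no", points: 0, source_quote: "0"}
  - {factor: sleep_disturbance, level: "yes", points: 3.3, source_quote: "3.3"}
  - {factor: smoking, level: never, points: 0, source_quote: "0"}
  - {factor: smoking, level: current, points: 7.9, source_quote: "7.9"}
  - {factor: social_activity, level: q1, points: 0, source_quote: "0"}
  - {factor: social_activity, level: q2, points: 0, source_quote: "0"}
  - {factor: social_activity, level: q3, points: 0, source_quote: "0"}
  - {factor: social_activity, level: q4, points: 6.5, source_quote: "6.5"}
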