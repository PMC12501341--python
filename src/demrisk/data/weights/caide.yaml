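# CAIDE (APOE-inclusive variant) point weights. Age bands follow the
# original midlife derivation (<47 / 47-53 / >53), resolved on baseline age
# with an integer-age convention (47-53 covers ages [47, 54)).
# Physical activity uses the index's own binary definition (active =
# at least 30 min at least twice per week), not the shared 3-level variable.
index: CAIDE
version: 1
source: published index weight table transcription
entries:
  - {factor: sex, level: female, points: 0, demographic: true, source_quote: "0"}
  - {factor: sex, level: male, points: 1, demographic: true, source_quote: "1"}
  - {factor: age, level: "<47", age_min: null, age_max: 47, points: 0, demographic: true, source_quote: "0"}
  - {factor: age, level: "47-53", age_min: 47, age_max: 54, points: 3, demographic: true, source_quote: "3"}
  - {factor: age, level: ">53", age_min: 54, age_max: null, points: 5, demographic: true, source_quote: "5"}
  - {factor: education_level, level: low, points: 4, demographic: true, source_quote: "4"}
  - {factor: education_level, level: medium, points: 3, demographic: true, source_quote: "3"}
  - {factor: education_level, level: high, points: 0, demographic: true, source_quote: "0"}
  - {factor: apoe_carrier, level: non_carrier, points: 0, source_quote: "0"}
  - {factor: apoe_carrier, level: carrier, points: 2, source_quote: "2"}
  - {factor: bmi, level: underweight, points: 0, source_quote: "0"}
  - {factor: bmi, level: normal, points: 0, source_quote: "0"}
  - {factor: bmi, level: overweight, points: 0, source_quote: "0"}
  - {factor: bmi, level: obese, points: 2, source_quote: "2"}
  - {factor: hypercholesterolemia, level: "no", points: 0, source_quote: "0"}
  - {factor: hypercholesterolemia, level: "yes", points: 1, source_quote: "1"}
  - {factor: hypertension, level: "no", points: 0, source_quote: "0"}
  - {factor: hypertension, level: "yes", points: 2, source_quote: "2"}
  - {factor: physical_activity_caide, level: active, points: 0, source_quote: "0"}
  - {factor: physical_activity_caide, level: inactive, points: 1, source_quote: "1"}
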