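{
  "trial_id": "HORIZON",
  "area_min_mm2": 1.25,
  "area_max_mm2": 17.5,
  "min_age_years": 55,
  "min_age_inclusive": false,
  "require_ga": true,
  "require_no_study_eye_cnv": true,
  "require_no_fellow_eye_cnv": false,
  "require_central_ga": false,
  "require_non_fovea_involving": false,
  "missing_fellow_policy": "strict",
  "notes": "Aged >55 with an eye free of CNV and GA area between 1.25 and 17.5 mm^2 inclusive. Fellow-eye CNV is not exclusionary here."
}
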