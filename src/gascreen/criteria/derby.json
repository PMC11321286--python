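{
  "trial_id": "DERBY",
  "area_min_mm2": 2.5,
  "area_max_mm2": 17.5,
  "min_age_years": 60,
  "min_age_inclusive": true,
  "require_ga": true,
  "require_no_study_eye_cnv": true,
  "require_no_fellow_eye_cnv": false,
  "require_central_ga": false,
  "require_non_fovea_involving": false,
  "missing_fellow_policy": "strict",
  "notes": "UNVERIFIED placeholder values except the 2.5 mm^2 lower area bound; age bound and upper area bound approximate the published protocol."
}
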