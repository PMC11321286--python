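{
  "trial_id": "GATHER2",
  "area_min_mm2": 2.5,
  "area_max_mm2": 17.5,
  "min_age_years": 50,
  "min_age_inclusive": true,
  "require_ga": true,
  "require_no_study_eye_cnv": true,
  "require_no_fellow_eye_cnv": true,
  "require_central_ga": true,
  "require_non_fovea_involving": true,
  "missing_fellow_policy": "strict",
  "notes": "UNVERIFIED placeholder values except: 2.5 mm^2 lower area bound, fellow-eye CNV exclusion, and the central non-fovea-involving location requirement."
}
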