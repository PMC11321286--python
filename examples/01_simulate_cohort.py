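"""Generate a small synthetic screening cohort and inspect its ground truth.

Each synthetic patient has two eyes with en-face RPE-presence masks (planted
atrophic lesions of known area), thickness maps with a foveal pit, diagnosis
flags, clinic letters, and simulated FAF grader measurements.
"""

from gascreen import CohortConfig, generate_cohort, load_bundled_criteria

horizon = load_bundled_criteria("horizon")
cfg = CohortConfig(n_patients=30, seed=11)
patients, gt = generate_cohort(cfg, criteria=[horizon])

n_ga_eyes = int(gt.ga.sum())
n_eligible = gt.groupby("patient_id")["patient_eligible_HORIZON"].first().sum()
print(f"patients: {len(patients)}, eyes: {len(gt)}, GA eyes: {n_ga_eyes}")
print(f"patients truly HORIZON-eligible: {n_eligible}")
print("\nfirst GA eyes (planted truth):")
cols = ["patient_id", "laterality", "true_area_mm2", "central_ga",
        "fovea_involving", "cnv"]
print(gt.loc[gt.ga, cols].head(5).to_string(index=False))
# true_area_mm2 is the analytic area of the planted lesion in mm^2;
# central_ga marks atrophy within 1500 um of the true fovea.
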