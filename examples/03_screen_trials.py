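"""Shortlist a synthetic cohort for several GA trials in all three modes.

Compares the imaging-based (AI) shortlist, the EHR keyword shortlist, and
their combination, across trial criteria that differ in area bounds,
fellow-eye CNV handling and lesion-location requirements.
"""

from gascreen import (
    CohortConfig,
    generate_cohort,
    keyword_search,
    load_bundled_criteria,
    profile_eye,
    shortlist,
)

cfg = CohortConfig(n_patients=80, seed=5)
patients, gt = generate_cohort(cfg)
profiles = {
    (p.patient_id, lat): profile_eye(eye, cfg.geometry)
    for p in patients
    for lat, eye in p.eyes.items()
}
flags = {
    p.patient_id: keyword_search(p.sorted_letters(), patient_id=p.patient_id)
    for p in patients
}

print(f"{'trial':<10} {'ai':>4} {'ehr':>4} {'combined':>9}")
for name in ("horizon", "derby", "gather2", "janssen"):
    crit = load_bundled_criteria(name)
    sizes = [
        len(shortlist(patients, profiles, crit, mode, flags))
        for mode in ("ai", "ehr", "combined")
    ]
    print(f"{crit.trial_id:<10} {sizes[0]:>4} {sizes[1]:>4} {sizes[2]:>9}")
# Stricter criteria (higher area floor, fellow-eye CNV exclusion, location
# requirements) shrink the AI shortlist; combined is always the intersection.
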