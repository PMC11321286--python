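"""Stratified validation statistics on the published worked example.

Feeds the printed validation counts (84/98 eligible in the AI+EHR stratum,
36/75 in AI-only, 7/81 in EHR-only) and shortlist sizes (1817 AI, 1729 EHR,
703 combined) through the PPV and weighted-yield estimators.
"""

import numpy as np

from gascreen import (
    StratumSample,
    ValidationTable,
    estimate_cohort_yield,
    ppv,
)
from gascreen.util import percent

table = ValidationTable(
    samples={
        "A1": StratumSample("A1", 98, 84),
        "A2": StratumSample("A2", 75, 36),
        "B1": StratumSample("B1", 81, 7),
    },
    populations={"A1": 703, "A2": 1817 - 703, "B1": 1729 - 703},
)

rng = np.random.default_rng(1)
for s in ("A1", "A2", "B1"):
    est = ppv(table.samples[s], rng=rng)
    lo, hi = est.ci_pct
    print(f"stratum {s}: PPV {est.point_pct}% (95% CI {lo}%-{hi}%)")

for target in ("ai", "ehr", "combined"):
    y = estimate_cohort_yield(table, target, rng=rng)
    print(
        f"{target:>8}: {y.count:.1f} of {y.shortlist_size} shortlisted "
        f"estimated eligible ({y.rate_pct}%)"
    )

ai = estimate_cohort_yield(table, "ai", rng=rng)
ehr = estimate_cohort_yield(table, "ehr", rng=rng)
comb = estimate_cohort_yield(table, "combined", rng=rng)
print(f"absolute improvement, AI vs EHR: {percent(ai.rate - ehr.rate)}%")
print(f"absolute improvement, combined vs EHR: {percent(comb.rate - ehr.rate)}%")
# The yield is the population-weighted sum of stratum PPVs: the AI shortlist
# covers strata A1+A2, the EHR shortlist A1+B1, the combined approach A1.
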