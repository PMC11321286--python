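# Methods

## Scope and data model

The package reimplements an imaging-plus-EHR prescreening pipeline for
geographic atrophy (GA) trials as a library operating on segmentation-derived
inputs: per-eye en-face RPE-presence masks and neurosensory-retina (NSR)
thickness maps with scan-geometry metadata, per-eye diagnosis flags (GA,
CNV, drusen — stand-ins for a classification network's thresholded outputs),
per-patient demographics and clinic letters, and declarative trial-criteria
configurations. Upstream deep segmentation/classification of raw OCT voxels
is out of scope; the synthetic-cohort generator supplies those inputs with
known ground truth.

All en-face arrays live on an `n_bscans × n_ascans` grid over an
`height_mm × width_mm` field. The default geometry is a common Topcon
macular-cube protocol, 128 B-scans × 512 A-scans over 6 × 6 mm, giving an
anisotropic pixel pitch (row pitch 46.9 μm, column pitch 11.7 μm); every
physical distance and area in the package respects that anisotropy.

## Area quantification

GA area is the count of RPE-absent pixels times the physical pixel area.
Before summation, absent-RPE connected components (8-connectivity) smaller
than `min_component_mm2` (default 0.05 mm²) are discarded: columnwise
absence is noise-sensitive in real segmentations, and a small-component
filter is the minimal defensible cleanup. The threshold is configurable and
the filter is exactly a no-op on the synthetic masks (planted lesions and
their foci are always larger). The diagnosis flag does not gate the area
computation — area is always measured, and the GA requirement is applied by
the eligibility rules, mirroring a two-step confirm-then-quantify workflow.

## Fovea localization

The anatomical fovea is approximated from the NSR thickness map: Gaussian
smoothing at `sigma_mm` = 0.25 mm (converted to an anisotropic pixel sigma),
then the argmin restricted to the central 50% window of the grid, ties
broken to the smallest (row, col). The window tolerates fixation offsets up
to roughly ±1.5 mm while excluding peripheral thinning. A constant map is
degenerate and returns the window center with a `RuntimeWarning`. This is a
deliberately simple, fully reproducible surrogate for proprietary fovea
detectors; no sub-pixel interpolation is attempted, so recovery is asserted
at ±3 px.

## Location criteria

*Central* GA: some atrophic pixel center within 1500 μm (inclusive) of the
fovea pixel center, pixel-center-to-pixel-center Euclidean distance in mm.
*Fovea-involving*: the fovea pixel itself is atrophic. Pixel presence (not
lesion-boundary distance) defines the criterion; on the default grid the
difference is at most half a pixel pitch. The vectorized implementation is
tested against an exhaustive per-pixel scan on small grids.

## Eligibility engine

A `TrialCriteria` is a declarative rule set: optional age bounds with the
comparison operator in the config (HORIZON's "aged >55" is strict), an
inclusive GA area window, study-eye CNV exclusion, optional fellow-eye CNV
exclusion, and optional location requirements (central, non-fovea-involving).
Each eye is evaluated as the study eye with the other eye as fellow; missing
fellow data under a fellow-eye rule follows a configurable policy (strict =
ineligible, the default, or lenient = ignore). A patient is eligible iff at
least one eye is. Verdicts enumerate every failed criterion, which makes
screening-failure audits straightforward.

Only the HORIZON configuration (1.25–17.5 mm² inclusive, >55 years, no
study-eye CNV) is fully specified from public sources; the DERBY, GATHER2
and Janssen configs carry the publicly reported structural differences
(2.5 mm² lower area bound; fellow-eye CNV exclusion for GATHER2/Janssen;
location requirements) with remaining values marked unverified in their
`notes`. The engine itself is criteria-agnostic.

## EHR search

Case-insensitive substring search with internal-whitespace normalization for
the literal keyword "geographic atrophy"; no stemming or negation handling,
because the point of this arm is to model what a naive keyword search does.
The earliest matching letter's date flags all scans acquired on or after it
(same-day inclusive: letters typically follow the visit that produced the
scan).

## Stratified validation and yield inference

Patients in AI ∪ EHR are stratified as A1 (both), A2 (AI only), B1 (EHR
only). The sampling pool requires FAF imaging of *both* eyes within ±90 days
of the OCT (inclusive at exactly 90). Per-stratum PPV is the graded eligible
fraction; a shortlist's expected eligible count is the population-weighted
sum of PPVs over the strata it covers (ai: A1+A2, ehr: A1+B1, combined: A1),
and its rate divides by the shortlist size. All CIs are percentile
bootstraps (not BCa), 10 000 resamples by default, seeded; the yield CI
resamples each stratum's validation outcomes independently (binomial
bootstrap) and propagates them through the weighted sum, matching the
stratified design. Resampling n binary outcomes with replacement is
implemented as a Binomial(n, p̂) draw, which is exact and vectorizable.

Reported percentages round half-up to whole percent in human-readable
output; machine outputs keep full precision. With the published validation
counts the estimators give 63% (AI), 40% (EHR) and 86% (combined) yields and
23% / 46% absolute improvements; eligible *counts* are reported unrounded
(e.g. 1137.3 for the AI arm) since the rounding convention behind published
integer counts is not recoverable, and whole-percent rates are the asserted
quantity.

In the synthetic pipeline the default validation outcome is the planted
ground-truth eligibility ("truth" mode), which makes the census-closure
property exact: sampling entire strata recovers the true eligible count
identically. A "graded" mode instead re-evaluates eligibility with the
grader-averaged FAF area, emulating reading-center noise. Synthetic PPVs in
truth mode are near-saturated for the AI strata (mismatches arise only from
lesions near an area bound or mis-located foveas), so the bundled generator
is a test harness for the inference machinery, not a simulator of real
screening-failure rates.

## Agreement statistics

Bland-Altman: mean difference and mean ± 1.96 × sd (n−1 denominator) limits
of agreement. ICC: single-measurement, absolute-agreement, two-way
mixed-effects form,

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

implemented directly from the two-way ANOVA decomposition in numpy so the
subject-level bootstrap vectorizes across resamples; `pingouin`'s
implementation serves as an independent cross-check in the test suite.
Constant rating matrices are degenerate and report ICC 0 with a warning.
The two-sided bootstrap group comparison recenters both groups to the pooled
mean (null of zero difference), resamples independently, and applies a
+1/(n_boot+1) continuity correction so p is never exactly 0.

## Synthetic cohort generator

The generator emulates the structure of a hospital screening cohort:

- **Lesions**: per-eye RPE-absence shapes (disc, ellipse, ring, multifocal
  with 2–3 foci) with analytic target areas drawn log-normal, median
  8.5 mm² (matching reported GA cohorts), log-sd 0.9, truncated below at
  0.25 mm². Centers are uniform within 1.8 mm of the fovea so all location
  classes occur. A pixel is atrophic when its center falls inside the shape,
  so the rasterized area differs from the target by at most one
  boundary-pixel band — the natural per-eye recovery tolerance. Lesions that
  would not fit the field at their drawn center are shrunk to the largest
  fitting area (and that fitted area recorded as truth): conservation of the
  planted area is kept exact in preference to the nominal upper truncation
  at 35 mm², which cannot fit a 6 mm field anyway.
- **Fovea signal**: baseline NSR thickness 300 μm with iid Gaussian noise
  (sd 3 μm) and a Gaussian pit (depth 120 μm, sigma 0.35 mm) at the true
  fovea. Preferred-retinal-locus misfixation translates the grid relative to
  the anatomical fovea by a uniform offset up to ±0.75 mm per axis.
- **Flags and dates**: per-patient GA prevalence 0.30 with bilateral
  probability 0.5; per-eye CNV 0.10 and drusen 0.30 (GA implies drusen);
  FAF dates offset uniformly within ±120 days of the OCT with 10% missing,
  so the ±90-day validation window genuinely filters.
- **Letters**: 80% of GA patients (2% of others) receive exactly one letter
  containing the keyword, dated before the earliest scan; decoy letters use
  near-miss phrases ("macular atrophy", "atrophic changes").
- **Graders**: two simulated graders report true area + grader bias
  (+0.3 / −0.3 mm²) + Gaussian noise (sd 1.5 mm²), clipped at 0 —
  enough structure for nontrivial Bland-Altman/ICC surfaces. The dual-grading
  adjudication workflow is represented only by averaging the two graders.

What the generator does **not** emulate: raw B-scan voxels, real
segmentation-error morphology (peripapillary atrophy, vessel shadows),
FAF/OCT modality differences, lesions extending beyond the field of view,
and realistic EHR language. Passing tests therefore demonstrate correctness
of the measurement and inference machinery on well-posed inputs, not
clinical performance on hospital data.

## Reproducibility and numerics

One master seed derives named substreams (CRC32 of the stream name into a
`SeedSequence`) for demographics, imaging, letters, grading, validation
sampling and bootstraps, so stages are independently reproducible and a
pipeline rerun with the same configuration is bit-identical (asserted by
comparing manifest digests; manifests deliberately contain no timestamps).
Dates are ISO-8601; percentages are only rounded in human-readable reports.
Problem sizes in the test and acceptance runs (cohorts of 50–150 patients,
200 recovery eyes, 200 simulated validation tables, 2 000-resample
bootstraps where a CI is only checked for coverage) were chosen to keep the
full suite under a minute while leaving every statistical check
well-powered; the estimators default to 10 000 resamples.

## Known limitations

- The fovea surrogate assumes a single global thickness minimum; eyes with
  severe cystic change or epiretinal membranes would need a robust detector.
- Percentile bootstrap CIs for proportions at n ≈ 80–100 undercover slightly
  (the calibration check accepts 90–98% coverage for nominal 95%).
- Non-imaging eligibility (visual acuity, media opacity, consent) is out of
  scope beyond age.
- The DERBY/GATHER2/Janssen criteria values are placeholders pending the
  trials' full published protocols; only their structure is meaningful.
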