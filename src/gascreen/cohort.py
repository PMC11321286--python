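"""Seeded synthetic cohorts with known ground truth.

Real GA screening cohorts are access-restricted hospital data, so every
downstream stage here is exercised on synthetic patients instead: each eye
carries an en-face RPE-presence mask with a planted atrophic lesion of known
area, shape and location, a neurosensory-retina thickness map with a smooth
foveal pit, classification flags (GA / CNV / drusen), clinic letters that may
or may not contain the literal keyword "geographic atrophy", FAF acquisition
dates offset from the OCT date, and two simulated human graders whose FAF
area measurements are the true area plus grader-specific bias and noise.

The generator records, per eye, the planted truth (area, fovea, location
flags) and, per patient, keyword status and true trial eligibility, so that
recovery of these quantities by the measurement pipeline can be checked
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .geometry import ScanGeometry
from .util import substream

LATERALITIES = ("L", "R")
LESION_SHAPES = ("disc", "ellipse", "ring", "multifocal")

_ETHNICITIES = ("White", "Asian", "Black", "Mixed", "Other", "Unknown")
_ETHNICITY_P = (0.45, 0.15, 0.08, 0.03, 0.04, 0.25)

#: Near-miss letter fragments that must NOT match a "geographic atrophy"
#: keyword search.
_DECOY_SENTENCES = (
    "Fundus examination shows atrophic changes at the macula.",
    "There is evidence of macular atrophy in the right eye.",
    "Scattered drusen noted at both maculae; no exudation.",
    "Dry AMD with pigmentary change; continue observation.",
    "Stable appearance; review in 6 months with OCT.",
)

_KEYWORD_SENTENCES = (
    "OCT confirms geographic atrophy involving the macula.",
    "Appearances are consistent with Geographic Atrophy secondary to AMD.",
    "Diagnosis: geographic atrophy, both eyes.",
)


@dataclass(frozen=True)
class LesionSpec:
    """Parametric description of one planted atrophic lesion.

    ``center_mm`` is the (x, y) offset of the lesion center from the true
    fovea, in mm (x along A-scans, y along B-scans).  ``target_area_mm2`` is
    the analytic area of the shape; the rasterized mask's pixel-counted area
    agrees with it to within one boundary-pixel band.
    """

    shape: str = "disc"
    center_mm: tuple[float, float] = (0.0, 0.0)
    target_area_mm2: float = 0.0
    n_foci: int = 1
    aspect: float = 1.6  # ellipse semi-axis ratio (x / y)
    inner_radius_mm: float = 0.5  # ring only

    def __post_init__(self) -> None:
        if self.shape not in LESION_SHAPES:
            raise InvalidConfigError(f"unknown lesion shape {self.shape!r}")
        if self.target_area_mm2 < 0:
            raise InvalidConfigError("target_area_mm2 must be >= 0")
        if self.n_foci < 1:
            raise InvalidConfigError("n_foci must be >= 1")
        if self.aspect <= 0 or self.inner_radius_mm < 0:
            raise InvalidConfigError("aspect must be > 0 and inner radius >= 0")

    def extent_mm(self) -> float:
        """Maximum distance from the lesion center to any lesion point."""
        a = self.target_area_mm2
        if a == 0:
            return 0.0
        if self.shape == "disc":
            return math.sqrt(a / math.pi)
        if self.shape == "ellipse":
            return math.sqrt(a * self.aspect / math.pi)
        if self.shape == "ring":
            return math.sqrt(a / math.pi + self.inner_radius_mm**2)
        # multifocal: foci ring radius + focus radius
        rf = math.sqrt(a / (self.n_foci * math.pi))
        return _foci_ring_radius(rf, self.n_foci) + rf


def _foci_ring_radius(rf: float, n: int) -> float:
    """Radius of the circle on which multifocal foci are placed.

    Chosen so adjacent foci of radius ``rf`` do not touch (30% clearance).
    """
    if n == 1:
        return 0.0
    return 1.3 * rf / math.sin(math.pi / n)


@dataclass
class EyeRecord:
    """One eye: segmentation-derived en-face maps plus stand-in diagnoses.

    ``rpe_present`` is True where the RPE layer was segmented as present;
    atrophy is its logical complement.  ``nsr_thickness`` is the neurosensory
    retina thickness in micrometres on the same grid.  The diagnosis flags
    stand in for a classification network's thresholded outputs.
    """

    laterality: str
    rpe_present: np.ndarray
    nsr_thickness: np.ndarray
    ga_flag: bool
    cnv_flag: bool
    drusen_flag: bool
    oct_date: date
    faf_date: date | None
    true_fovea_px: tuple[int, int]
    true_area_mm2: float
    lesion: LesionSpec | None = None

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise InvalidConfigError(f"laterality must be L or R, got {self.laterality!r}")
        if self.rpe_present.shape != self.nsr_thickness.shape:
            raise InvalidConfigError("mask and thickness map must share one grid")
        if np.any(self.nsr_thickness < 0):
            raise InvalidConfigError("thickness must be non-negative")


@dataclass
class PatientRecord:
    """Demographics, up to two eyes, clinic letters and FAF gradings."""

    patient_id: str
    age_years: float
    sex: str
    ethnicity: str
    imd_decile: int
    eyes: dict = field(default_factory=dict)  # laterality -> EyeRecord
    letters: list = field(default_factory=list)  # [(date, text)], date-sorted
    faf_gradings: list = field(default_factory=list)  # [(laterality, grader, mm2)]
    passes_inclusion: bool = True

    def sorted_letters(self) -> list[tuple[date, str]]:
        return sorted(self.letters, key=lambda dt: dt[0])


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Lesion areas follow a log-normal with median 8.5 mm^2 (matching reported
    GA cohorts) truncated below at 0.25 mm^2 and above at the largest area
    whose shape fits the scan field, so every planted lesion is fully
    contained and its area is exactly known.
    """

    n_patients: int
    seed: int = 0
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    ga_prevalence: float = 0.30
    bilateral_ga_prob: float = 0.5
    cnv_prevalence: float = 0.10
    drusen_prevalence: float = 0.30
    lesion_median_mm2: float = 8.5
    lesion_sigma_log: float = 0.9
    lesion_area_min_mm2: float = 0.25
    lesion_area_max_mm2: float = 35.0
    lesion_offset_max_mm: float = 1.8
    keyword_frac_ga: float = 0.8
    keyword_frac_non_ga: float = 0.02
    grader_noise_sd_mm2: float = 1.5
    grader_biases_mm2: tuple[float, float] = (0.3, -0.3)
    faf_offset_max_days: int = 120
    faf_missing_prob: float = 0.10
    misfixation_max_mm: float = 0.75
    fovea_pit_depth_um: float = 120.0
    fovea_pit_sigma_mm: float = 0.35
    baseline_thickness_um: float = 300.0
    thickness_noise_sd_um: float = 3.0
    age_mean: float = 78.0
    age_sd: float = 9.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise InvalidConfigError("n_patients must be > 0")
        for name in (
            "ga_prevalence",
            "bilateral_ga_prob",
            "cnv_prevalence",
            "drusen_prevalence",
            "keyword_frac_ga",
            "keyword_frac_non_ga",
            "faf_missing_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.grader_noise_sd_mm2 < 0:
            raise InvalidConfigError("grader noise sd must be >= 0")
        if not 0 < self.lesion_area_min_mm2 <= self.lesion_area_max_mm2:
            raise InvalidConfigError("lesion area bounds must satisfy 0 < min <= max")


# ---------------------------------------------------------------------------
# Lesion rendering
# ---------------------------------------------------------------------------


def render_lesion(
    spec: LesionSpec, geometry: ScanGeometry, fovea_px: tuple[int, int]
) -> np.ndarray:
    """Rasterize a lesion spec into an en-face mask of RPE *absence*.

    A pixel is marked absent when its physical center lies inside the
    analytic shape; the pixel-counted area therefore differs from
    ``target_area_mm2`` by at most one boundary-pixel band.

    Parameters
    ----------
    spec : LesionSpec
    geometry : ScanGeometry
    fovea_px : (row, col)
        True fovea position; ``spec.center_mm`` is relative to it.

    Returns
    -------
    numpy.ndarray of bool, shape ``geometry.shape``
        True where the RPE is absent.
    """
    mask = np.zeros(geometry.shape, dtype=bool)
    if spec.target_area_mm2 == 0:
        return mask

    Y, X = geometry.pixel_centers_mm()
    fy, fx = geometry.px_to_mm(*fovea_px)
    cx = fx + spec.center_mm[0]
    cy = fy + spec.center_mm[1]
    a = spec.target_area_mm2

    if spec.shape == "disc":
        r2 = a / math.pi
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r2
    elif spec.shape == "ellipse":
        sa = math.sqrt(a * spec.aspect / math.pi)  # semi-axis along x
        sb = sa / spec.aspect
        mask = ((X - cx) / sa) ** 2 + ((Y - cy) / sb) ** 2 <= 1.0
    elif spec.shape == "ring":
        ri = spec.inner_radius_mm
        ro2 = a / math.pi + ri**2
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        mask = (d2 <= ro2) & (d2 >= ri**2)
    else:  # multifocal
        n = spec.n_foci
        rf2 = a / (n * math.pi)
        ring_r = _foci_ring_radius(math.sqrt(rf2), n)
        for k in range(n):
            th = 2.0 * math.pi * k / n
            ox = cx + ring_r * math.cos(th)
            oy = cy + ring_r * math.sin(th)
            mask |= (X - ox) ** 2 + (Y - oy) ** 2 <= rf2
    return mask


def rendering_tolerance_mm2(mask: np.ndarray, geometry: ScanGeometry) -> float:
    """One boundary-pixel band of a mask, in mm^2.

    The rasterized area can differ from the analytic target by at most the
    number of boundary pixels times the pixel area; this is the natural
    per-eye tolerance for planted-area recovery.
    """
    from scipy import ndimage

    if not mask.any():
        return geometry.pixel_area_mm2
    interior = ndimage.binary_erosion(mask)
    n_boundary = int(mask.sum() - interior.sum())
    return max(n_boundary, 1) * geometry.pixel_area_mm2


def _max_area_for_extent(spec: LesionSpec, extent: float) -> float:
    """Largest target area for which ``spec``'s shape stays within ``extent``."""
    if extent <= 0:
        return 0.0
    if spec.shape == "disc":
        return math.pi * extent**2
    if spec.shape == "ellipse":
        return math.pi * extent**2 / spec.aspect
    if spec.shape == "ring":
        if extent <= spec.inner_radius_mm:
            return 0.0
        return math.pi * (extent**2 - spec.inner_radius_mm**2)
    n = spec.n_foci
    rf = extent / (1.0 + 1.3 / math.sin(math.pi / n)) if n > 1 else extent
    return n * math.pi * rf**2


def fit_lesion_to_field(
    spec: LesionSpec, geometry: ScanGeometry, fovea_px: tuple[int, int]
) -> LesionSpec:
    """Shrink a lesion's target area, if needed, so it fits the field of view.

    Keeps the shape and center; reduces the area to the largest value whose
    extent stays one pixel pitch inside every field edge.  Needed because a
    nominally drawn area (e.g. a 35 mm^2 disc) may not fit a 6 x 6 mm field.
    """
    fy, fx = geometry.px_to_mm(*fovea_px)
    cx = fx + spec.center_mm[0]
    cy = fy + spec.center_mm[1]
    margin = max(geometry.row_pitch_mm, geometry.col_pitch_mm)
    emax = min(cx, geometry.width_mm - cx, cy, geometry.height_mm - cy) - margin
    if spec.extent_mm() <= emax:
        return spec
    if spec.shape == "ring" and emax <= spec.inner_radius_mm:
        spec = replace(spec, shape="disc")
    a_max = max(_max_area_for_extent(spec, emax), 0.0)
    return replace(spec, target_area_mm2=min(spec.target_area_mm2, a_max))


# ---------------------------------------------------------------------------
# Letters
# ---------------------------------------------------------------------------


def synthesize_letters(
    patient: PatientRecord,
    include_keyword: bool,
    keyword_date: date,
    rng: np.random.Generator,
    n_decoys: int = 2,
) -> list[tuple[date, str]]:
    """Attach clinic letters to a patient and return the updated list.

    When ``include_keyword`` is set, exactly one letter (dated
    ``keyword_date``) contains the literal phrase "geographic atrophy"
    (case randomized to exercise case-insensitive search).  All other
    letters are decoys built from near-miss phrases ("atrophic changes",
    "macular atrophy") that must not match the keyword.
    """
    letters = list(patient.letters)
    for _ in range(n_decoys):
        offset = int(rng.integers(-700, 700))
        body = rng.choice(_DECOY_SENTENCES)
        letters.append((keyword_date + timedelta(days=offset), str(body)))
    if include_keyword:
        body = str(rng.choice(_KEYWORD_SENTENCES))
        letters.append((keyword_date, body))
    letters.sort(key=lambda dt: dt[0])
    patient.letters = letters
    return letters


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_lesion_spec(cfg: CohortConfig, rng: np.random.Generator) -> LesionSpec:
    area = float(
        np.exp(rng.normal(math.log(cfg.lesion_median_mm2), cfg.lesion_sigma_log))
    )
    area = float(np.clip(area, cfg.lesion_area_min_mm2, cfg.lesion_area_max_mm2))
    r = cfg.lesion_offset_max_mm * math.sqrt(rng.uniform())
    th = rng.uniform(0.0, 2.0 * math.pi)
    center = (r * math.cos(th), r * math.sin(th))
    shape = rng.choice(LESION_SHAPES, p=[0.40, 0.30, 0.05, 0.25])
    n_foci = int(rng.integers(2, 4)) if shape == "multifocal" else 1
    return LesionSpec(
        shape=str(shape), center_mm=center, target_area_mm2=area, n_foci=n_foci
    )


def _thickness_map(
    cfg: CohortConfig, geometry: ScanGeometry, fovea_px: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Baseline thickness with a Gaussian foveal pit and low-amplitude noise."""
    Y, X = geometry.pixel_centers_mm()
    fy, fx = geometry.px_to_mm(*fovea_px)
    d2 = (X - fx) ** 2 + (Y - fy) ** 2
    pit = cfg.fovea_pit_depth_um * np.exp(-d2 / (2.0 * cfg.fovea_pit_sigma_mm**2))
    noise = rng.normal(0.0, cfg.thickness_noise_sd_um, size=geometry.shape)
    return np.clip(cfg.baseline_thickness_um - pit + noise, 0.0, None)


def _location_flags(
    mask: np.ndarray,
    fovea_px: tuple[int, int],
    geometry: ScanGeometry,
    radius_um: float = 1500.0,
) -> tuple[bool, bool]:
    """Ground-truth central / fovea-involving flags for a planted mask.

    Direct distance computation from the true fovea's pixel center to every
    atrophic pixel center, with anisotropic pitch.
    """
    if not mask.any():
        return (False, False)
    rows, cols = np.nonzero(mask)
    dy = (rows - fovea_px[0]) * geometry.row_pitch_mm
    dx = (cols - fovea_px[1]) * geometry.col_pitch_mm
    central = bool(np.min(dy**2 + dx**2) <= (radius_um / 1000.0) ** 2)
    involving = bool(mask[fovea_px[0], fovea_px[1]])
    return (central, involving)


def generate_cohort(
    config: CohortConfig, criteria: list | None = None
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a synthetic cohort and its ground-truth table.

    Parameters
    ----------
    config : CohortConfig
    criteria : list of TrialCriteria, optional
        When given, the ground-truth table additionally records each eye's
        and patient's *true* eligibility (planted area and flags against the
        trial rules) under a column per trial.

    Returns
    -------
    (patients, ground_truth)
        ``patients`` is a list of :class:`PatientRecord`; ``ground_truth``
        a DataFrame with one row per eye.

    Notes
    -----
    Deterministic for a fixed config (the seed lives inside the config): the
    demographic, imaging, letter and grading substreams are derived from the
    master seed by name.
    """
    geom = config.geometry
    rng_demo = substream(config.seed, "cohort.demographics")
    rng_img = substream(config.seed, "cohort.imaging")
    rng_let = substream(config.seed, "cohort.letters")
    rng_grd = substream(config.seed, "cohort.grading")

    base_date = date(2018, 1, 1)
    patients: list[PatientRecord] = []
    gt_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age = float(np.clip(rng_demo.normal(config.age_mean, config.age_sd), 50, 100))
        sex = "F" if rng_demo.uniform() < 0.55 else "M"
        ethnicity = str(rng_demo.choice(_ETHNICITIES, p=_ETHNICITY_P))
        imd = int(rng_demo.integers(1, 11))
        patient = PatientRecord(
            patient_id=pid, age_years=age, sex=sex, ethnicity=ethnicity,
            imd_decile=imd,
        )

        ga_patient = rng_img.uniform() < config.ga_prevalence
        first_ga_eye = str(rng_img.choice(LATERALITIES))
        eye_has_ga = {
            lat: ga_patient
            and (lat == first_ga_eye or rng_img.uniform() < config.bilateral_ga_prob)
            for lat in LATERALITIES
        }

        earliest_oct = None
        for lat in LATERALITIES:
            oct_date = base_date + timedelta(days=int(rng_img.integers(0, 1461)))
            earliest_oct = min(earliest_oct or oct_date, oct_date)
            # preferred-retinal-locus misfixation: the scan grid center is
            # offset from the anatomical fovea by up to +-misfixation_max_mm
            dy = rng_img.uniform(-config.misfixation_max_mm, config.misfixation_max_mm)
            dx = rng_img.uniform(-config.misfixation_max_mm, config.misfixation_max_mm)
            fovea_px = geom.mm_to_px(geom.height_mm / 2 + dy, geom.width_mm / 2 + dx)
            thickness = _thickness_map(config, geom, fovea_px, rng_img)

            ga = bool(eye_has_ga[lat])
            cnv = bool(rng_img.uniform() < config.cnv_prevalence)
            drusen = bool(rng_img.uniform() < config.drusen_prevalence) or ga
            lesion = None
            mask = np.zeros(geom.shape, dtype=bool)
            true_area = 0.0
            if ga:
                lesion = _draw_lesion_spec(config, rng_img)
                lesion = fit_lesion_to_field(lesion, geom, fovea_px)
                mask = render_lesion(lesion, geom, fovea_px)
                true_area = lesion.target_area_mm2

            faf_date = None
            if rng_img.uniform() >= config.faf_missing_prob:
                off = int(
                    rng_img.integers(
                        -config.faf_offset_max_days, config.faf_offset_max_days + 1
                    )
                )
                faf_date = oct_date + timedelta(days=off)

            eye = EyeRecord(
                laterality=lat,
                rpe_present=~mask,
                nsr_thickness=thickness,
                ga_flag=ga,
                cnv_flag=cnv,
                drusen_flag=drusen,
                oct_date=oct_date,
                faf_date=faf_date,
                true_fovea_px=fovea_px,
                true_area_mm2=true_area,
                lesion=lesion,
            )
            patient.eyes[lat] = eye

            central, involving = _location_flags(mask, fovea_px, geom)
            gt_rows.append(
                {
                    "patient_id": pid,
                    "laterality": lat,
                    "ga": ga,
                    "cnv": cnv,
                    "drusen": drusen,
                    "true_area_mm2": true_area,
                    "fovea_row": fovea_px[0],
                    "fovea_col": fovea_px[1],
                    "central_ga": central,
                    "fovea_involving": involving,
                }
            )

            if ga:
                for g, bias in enumerate(config.grader_biases_mm2):
                    graded = max(
                        0.0,
                        true_area
                        + bias
                        + float(rng_grd.normal(0.0, config.grader_noise_sd_mm2)),
                    )
                    patient.faf_gradings.append((lat, f"grader_{g + 1}", graded))

        # letters: keyword letters predate the earliest scan so that the
        # scan itself is flagged by the EHR search
        frac = config.keyword_frac_ga if ga_patient else config.keyword_frac_non_ga
        include_kw = rng_let.uniform() < frac
        kw_date = earliest_oct - timedelta(days=int(rng_let.integers(10, 400)))
        synthesize_letters(patient, include_kw, kw_date, rng_let)

        patients.append(patient)
        for row in gt_rows[-2:]:
            row["keyword"] = include_kw
            row["age_years"] = age

    ground_truth = pd.DataFrame(gt_rows)

    if criteria:
        from .eligibility import true_eligibility

        for crit in criteria:
            eye_col, pat_col = true_eligibility(patients, ground_truth, crit)
            ground_truth[f"eye_eligible_{crit.trial_id}"] = eye_col
            ground_truth[f"patient_eligible_{crit.trial_id}"] = pat_col

    return patients, ground_truth
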