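"""Declarative trial-eligibility engine.

GA interventional trials share a small vocabulary of imaging criteria —
age range, GA area window (inclusive bounds, in mm^2), whether CNV in the
study or fellow eye is exclusionary, and requirements on lesion location
relative to the fovea (central GA, sparing of the foveal center point).
A :class:`TrialCriteria` captures one trial's rule set declaratively; the
engine evaluates each eye as the study eye with the other eye as fellow,
and a patient qualifies when at least one eye does.

The bundled HORIZON configuration carries fully specified values (age >55,
no CNV, GA area between 1.25 and 17.5 mm^2 inclusive).  The DERBY, GATHER2
and Janssen configurations carry the structural differences publicly
reported (2.5 mm^2 lower area bound; fellow-eye CNV exclusion for GATHER2
and Janssen; central, non-fovea-involving location requirements) with
placeholder values marked unverified in their ``notes`` field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .errors import DataError, InvalidConfigError
from .metrics import ImagingProfile

_FAIL_TAGS = (
    "ga_absent",
    "age_below_min",
    "age_above_max",
    "area_below_min",
    "area_above_max",
    "study_eye_cnv",
    "fellow_eye_cnv",
    "fellow_eye_unknown",
    "not_central",
    "fovea_involving",
)


@dataclass(frozen=True)
class TrialCriteria:
    """One trial's imaging eligibility rule set.

    Area bounds are inclusive at both ends.  The age comparison operator is
    part of the configuration: ``min_age_inclusive=False`` encodes a strict
    ">" (as in HORIZON's "aged >55").  ``missing_fellow_policy`` governs eyes
    whose fellow-eye CNV status is unknown when the trial excludes fellow-eye
    CNV: "strict" treats them as ineligible, "lenient" ignores the check.
    """

    trial_id: str
    area_min_mm2: float = 0.0
    area_max_mm2: float = float("inf")
    min_age_years: float | None = None
    min_age_inclusive: bool = False
    max_age_years: float | None = None
    max_age_inclusive: bool = True
    require_ga: bool = True
    require_no_study_eye_cnv: bool = True
    require_no_fellow_eye_cnv: bool = False
    require_central_ga: bool = False
    require_non_fovea_involving: bool = False
    missing_fellow_policy: str = "strict"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.area_min_mm2 < 0 or self.area_max_mm2 < 0:
            raise InvalidConfigError("area bounds must be >= 0")
        if self.area_min_mm2 > self.area_max_mm2:
            raise InvalidConfigError(
                f"area_min_mm2 ({self.area_min_mm2}) exceeds "
                f"area_max_mm2 ({self.area_max_mm2})"
            )
        if self.missing_fellow_policy not in ("strict", "lenient"):
            raise InvalidConfigError(
                "missing_fellow_policy must be 'strict' or 'lenient'"
            )

    def to_json(self) -> str:
        d = asdict(self)
        if d["area_max_mm2"] == float("inf"):
            d["area_max_mm2"] = None
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialCriteria":
        d = dict(d)
        if d.get("area_max_mm2") is None:
            d["area_max_mm2"] = float("inf")
        try:
            return cls(**d)
        except TypeError as exc:
            raise DataError(f"invalid criteria field: {exc}") from exc

    @classmethod
    def from_json(cls, text: str) -> "TrialCriteria":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise DataError(f"criteria JSON parse error: {exc}") from exc
        return cls.from_dict(d)


def load_bundled_criteria(name: str) -> TrialCriteria:
    """Load one of the shipped trial configurations by name.

    Available: "horizon", "derby", "gather2", "janssen".
    """
    ref = resources.files("gascreen.criteria").joinpath(f"{name.lower()}.json")
    return TrialCriteria.from_json(ref.read_text())


@dataclass
class EyeVerdict:
    """Per-eye eligibility outcome with the criteria that failed."""

    laterality: str
    eligible: bool
    failed: list = field(default_factory=list)


@dataclass
class EligibilityResult:
    """Patient-level outcome: eligible iff at least one eye verdict is."""

    patient_id: str
    eye_verdicts: dict  # laterality -> EyeVerdict
    patient_eligible: bool


def evaluate_eye(
    profile: ImagingProfile,
    ga_flag: bool,
    cnv_flag: bool,
    fellow_cnv_flag: bool | None,
    age_years: float,
    criteria: TrialCriteria,
    laterality: str = "?",
) -> EyeVerdict:
    """Evaluate one study eye against a trial's rule set.

    All enabled criteria must pass; the returned verdict enumerates every
    failed criterion (not just the first).  Area bounds are inclusive.
    """
    failed: list[str] = []
    if criteria.require_ga and not ga_flag:
        failed.append("ga_absent")
    if criteria.min_age_years is not None:
        ok = (
            age_years >= criteria.min_age_years
            if criteria.min_age_inclusive
            else age_years > criteria.min_age_years
        )
        if not ok:
            failed.append("age_below_min")
    if criteria.max_age_years is not None:
        ok = (
            age_years <= criteria.max_age_years
            if criteria.max_age_inclusive
            else age_years < criteria.max_age_years
        )
        if not ok:
            failed.append("age_above_max")
    if profile.area_mm2 < criteria.area_min_mm2:
        failed.append("area_below_min")
    if profile.area_mm2 > criteria.area_max_mm2:
        failed.append("area_above_max")
    if criteria.require_no_study_eye_cnv and cnv_flag:
        failed.append("study_eye_cnv")
    if criteria.require_no_fellow_eye_cnv:
        if fellow_cnv_flag is None:
            if criteria.missing_fellow_policy == "strict":
                failed.append("fellow_eye_unknown")
        elif fellow_cnv_flag:
            failed.append("fellow_eye_cnv")
    if criteria.require_central_ga and not profile.central_ga:
        failed.append("not_central")
    if criteria.require_non_fovea_involving and profile.fovea_involving:
        failed.append("fovea_involving")
    return EyeVerdict(laterality=laterality, eligible=not failed, failed=failed)


def evaluate_patient(
    patient_id: str,
    age_years: float,
    eye_inputs: Mapping[str, tuple[ImagingProfile, bool, bool]],
    criteria: TrialCriteria,
) -> EligibilityResult:
    """Evaluate a patient: each eye as study eye, the other as fellow.

    ``eye_inputs`` maps laterality -> (profile, ga_flag, cnv_flag).  A
    missing fellow eye yields ``fellow_cnv_flag=None`` (policy applies).
    """
    verdicts: dict[str, EyeVerdict] = {}
    for lat, (profile, ga, cnv) in eye_inputs.items():
        fellow_lat = "R" if lat == "L" else "L"
        fellow = eye_inputs.get(fellow_lat)
        fellow_cnv = fellow[2] if fellow is not None else None
        verdicts[lat] = evaluate_eye(
            profile, ga, cnv, fellow_cnv, age_years, criteria, laterality=lat
        )
    return EligibilityResult(
        patient_id=patient_id,
        eye_verdicts=verdicts,
        patient_eligible=any(v.eligible for v in verdicts.values()),
    )


SHORTLIST_MODES = ("ai", "ehr", "combined")


def shortlist(
    patients: Iterable,
    profiles: Mapping[tuple[str, str], ImagingProfile],
    criteria: TrialCriteria,
    mode: str,
    ehr_flags: Mapping[str, object] | None = None,
) -> list[str]:
    """Produce the sorted shortlist of patient ids for one trial and mode.

    - ``ai``: patients with at least one eligible eye under ``criteria``;
    - ``ehr``: patients whose keyword flag precedes (or equals) at least one
      scan date;
    - ``combined``: the intersection (EHR search narrowed by the imaging
      criteria).

    ``profiles`` maps (patient_id, laterality) to the eye's imaging profile.
    """
    if mode not in SHORTLIST_MODES:
        raise InvalidConfigError(
            f"unknown mode {mode!r}; expected one of {SHORTLIST_MODES}"
        )

    def ai_set() -> set[str]:
        out = set()
        for p in patients_list:
            eye_inputs = {
                lat: (profiles[(p.patient_id, lat)], eye.ga_flag, eye.cnv_flag)
                for lat, eye in p.eyes.items()
                if (p.patient_id, lat) in profiles
            }
            if not eye_inputs:
                continue
            res = evaluate_patient(p.patient_id, p.age_years, eye_inputs, criteria)
            if res.patient_eligible:
                out.add(p.patient_id)
        return out

    def ehr_set() -> set[str]:
        if ehr_flags is None:
            raise InvalidConfigError("ehr/combined mode requires ehr_flags")
        from .ehr import flag_scans

        out = set()
        for p in patients_list:
            flag = ehr_flags.get(p.patient_id)
            if flag is None or not flag.matched:
                continue
            scan_dates = [eye.oct_date for eye in p.eyes.values()]
            if any(flag_scans(flag, scan_dates)):
                out.add(p.patient_id)
        return out

    patients_list = list(patients)
    if mode == "ai":
        ids = ai_set()
    elif mode == "ehr":
        ids = ehr_set()
    else:
        ids = ai_set() & ehr_set()
    return sorted(ids)


def true_eligibility(patients, ground_truth, criteria: TrialCriteria):
    """Ground-truth eligibility columns from planted areas and flags.

    Uses the *planted* lesion area and true location flags (not the measured
    profile), so it is the reference against which the measurement pipeline's
    shortlist is validated.  Returns (eye_eligible, patient_eligible) lists
    aligned with the ground-truth table's rows.
    """
    cnv_by_eye = {
        (r.patient_id, r.laterality): bool(r.cnv)
        for r in ground_truth.itertuples()
    }
    eye_col: list[bool] = []
    for r in ground_truth.itertuples():
        profile = ImagingProfile(
            area_mm2=float(r.true_area_mm2),
            central_ga=bool(r.central_ga),
            fovea_involving=bool(r.fovea_involving),
            fovea_px=(int(r.fovea_row), int(r.fovea_col)),
            atrophy_mask=None,
            is_ga=bool(r.ga),
        )
        fellow_lat = "R" if r.laterality == "L" else "L"
        fellow_cnv = cnv_by_eye.get((r.patient_id, fellow_lat))
        verdict = evaluate_eye(
            profile,
            bool(r.ga),
            bool(r.cnv),
            fellow_cnv,
            float(r.age_years),
            criteria,
            laterality=r.laterality,
        )
        eye_col.append(verdict.eligible)
    by_patient: dict[str, bool] = {}
    for elig, pid in zip(eye_col, ground_truth["patient_id"]):
        by_patient[pid] = by_patient.get(pid, False) or elig
    pat_col = [by_patient[pid] for pid in ground_truth["patient_id"]]
    return eye_col, pat_col
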