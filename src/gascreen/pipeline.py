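"""End-to-end screening pipeline driver.

One call reproduces the whole study flow on a synthetic cohort: generate
patients -> profile every eye (area, fovea, location) -> run the EHR keyword
search -> build AI / EHR / combined shortlists per trial -> stratify,
sample and grade the clinical validation -> infer per-shortlist yields and
agreement statistics -> write everything with a manifest.

A single master seed drives named substreams for cohort generation,
validation sampling and every bootstrap, so a rerun with the same
configuration is bit-identical and each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cohort import CohortConfig, generate_cohort
from .ehr import keyword_search
from .eligibility import TrialCriteria, shortlist
from .errors import GascreenError
from .metrics import profile_eye
from .stats import (
    AgreementPair,
    StratumSample,
    ValidationTable,
    assign_strata,
    bland_altman,
    bootstrap_group_compare,
    estimate_cohort_yield,
    faf_available,
    icc_agreement,
    ppv,
    sample_for_validation,
)
from .util import percent, round_half_up, substream


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``validation_n`` caps the per-stratum validation sample (None = census of
    the FAF-filtered pool).  ``validation_outcome`` selects how sampled
    patients are graded: "truth" uses the planted ground-truth eligibility
    (exact), "graded" re-evaluates eligibility with the grader-averaged FAF
    area in place of the planted area (noisy, as in a real reading-center
    workflow).
    """

    cohort: CohortConfig
    criteria: list[TrialCriteria]
    seed: int = 0
    out_dir: str | Path | None = None
    validation_n: int | None = None
    n_boot: int = 10_000
    faf_window_days: int = 90
    validation_outcome: str = "truth"
    write_maps: bool = False

    def __post_init__(self) -> None:
        if not self.criteria:
            raise GascreenError("at least one trial criteria set is required")
        if self.validation_outcome not in ("truth", "graded"):
            raise GascreenError("validation_outcome must be 'truth' or 'graded'")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    patients: list
    ground_truth: pd.DataFrame
    profiles: dict
    ehr_flags: dict
    shortlists: dict  # (trial_id, mode) -> [patient_id]
    strata: dict  # patient_id -> stratum (primary trial)
    validation_table: ValidationTable
    report: dict
    out_dir: Path | None = None


def _graded_area(patient, laterality: str) -> float | None:
    areas = [a for lat, _g, a in patient.faf_gradings if lat == laterality]
    return float(np.mean(areas)) if areas else None


def _validation_outcomes(
    sampled_ids: list[str],
    patients_by_id: dict,
    ground_truth: pd.DataFrame,
    criteria: TrialCriteria,
    outcome: str,
) -> int:
    """Number of sampled patients truly eligible under the primary trial."""
    col = f"patient_eligible_{criteria.trial_id}"
    if outcome == "truth":
        per_patient = ground_truth.groupby("patient_id")[col].first()
        return int(sum(bool(per_patient[pid]) for pid in sampled_ids))

    # graded: substitute the grader-averaged FAF area for the planted area
    from .eligibility import evaluate_eye
    from .metrics import ImagingProfile

    n_eligible = 0
    gt = ground_truth.set_index(["patient_id", "laterality"])
    for pid in sampled_ids:
        p = patients_by_id[pid]
        eligible = False
        for lat, eye in p.eyes.items():
            row = gt.loc[(pid, lat)]
            area = _graded_area(p, lat)
            if area is None:
                area = 0.0
            fellow = p.eyes.get("R" if lat == "L" else "L")
            profile = ImagingProfile(
                area_mm2=area,
                central_ga=bool(row.central_ga) and area > 0,
                fovea_involving=bool(row.fovea_involving) and area > 0,
                fovea_px=(int(row.fovea_row), int(row.fovea_col)),
                atrophy_mask=None,
                is_ga=bool(eye.ga_flag),
            )
            verdict = evaluate_eye(
                profile,
                eye.ga_flag,
                eye.cnv_flag,
                fellow.cnv_flag if fellow else None,
                p.age_years,
                criteria,
                laterality=lat,
            )
            eligible = eligible or verdict.eligible
        n_eligible += int(eligible)
    return n_eligible


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screening pipeline; see :class:`PipelineConfig`.

    When ``config.out_dir`` is set, all declared outputs plus a manifest are
    written there; on failure a ``_FAILED`` marker naming the error is left
    in the directory.
    """
    out = Path(config.out_dir) if config.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(config, out)
    except Exception as exc:
        if out is not None:
            (out / "_FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return result


def _run(config: PipelineConfig, out: Path | None) -> PipelineResult:
    master = config.seed
    cohort_seed = int(substream(master, "pipeline.cohort").integers(2**31))
    cohort_cfg = replace(config.cohort, seed=cohort_seed)
    patients, ground_truth = generate_cohort(cohort_cfg, config.criteria)
    geometry = cohort_cfg.geometry
    patients_by_id = {p.patient_id: p for p in patients}

    # --- imaging profiles -------------------------------------------------
    profiles = {
        (p.patient_id, lat): profile_eye(eye, geometry)
        for p in patients
        for lat, eye in p.eyes.items()
    }

    # --- EHR search -------------------------------------------------------
    ehr_flags = {
        p.patient_id: keyword_search(p.sorted_letters(), patient_id=p.patient_id)
        for p in patients
    }

    # --- shortlists -------------------------------------------------------
    shortlists: dict[tuple[str, str], list[str]] = {}
    for crit in config.criteria:
        for mode in ("ai", "ehr", "combined"):
            shortlists[(crit.trial_id, mode)] = shortlist(
                patients, profiles, crit, mode, ehr_flags
            )

    # --- clinical validation on the primary (first) trial ------------------
    primary = config.criteria[0]
    ai_ids = shortlists[(primary.trial_id, "ai")]
    ehr_ids = shortlists[(primary.trial_id, "ehr")]
    strata = assign_strata(ai_ids, ehr_ids)

    rng_sample = substream(master, "pipeline.validation_sampling")
    rng_boot = substream(master, "pipeline.bootstrap")

    samples: dict[str, StratumSample] = {}
    populations: dict[str, int] = {}
    sampled_ids: dict[str, list[str]] = {}
    for s in ("A1", "A2", "B1"):
        members = [patients_by_id[pid] for pid, lab in strata.items() if lab == s]
        populations[s] = len(members)
        pool_size = sum(faf_available(p, config.faf_window_days) for p in members)
        n = pool_size if config.validation_n is None else min(
            config.validation_n, pool_size
        )
        ids = (
            sample_for_validation(members, n, rng_sample, config.faf_window_days)
            if n > 0
            else []
        )
        sampled_ids[s] = ids
        n_elig = _validation_outcomes(
            ids, patients_by_id, ground_truth, primary, config.validation_outcome
        )
        samples[s] = StratumSample(stratum=s, n_sampled=n, n_eligible=n_elig)
    table = ValidationTable(samples=samples, populations=populations)

    # --- inference ---------------------------------------------------------
    report: dict = {
        "primary_trial": primary.trial_id,
        "seed": master,
        "n_patients": config.cohort.n_patients,
        "shortlist_sizes": {
            f"{tid}:{mode}": len(ids) for (tid, mode), ids in shortlists.items()
        },
        "strata_populations": populations,
        "validation_samples": {
            s: {"n_sampled": sm.n_sampled, "n_eligible": sm.n_eligible}
            for s, sm in samples.items()
        },
    }
    ppvs = {}
    for s, sm in samples.items():
        if sm.n_sampled > 0:
            est = ppv(sm, n_boot=config.n_boot, rng=rng_boot)
            ppvs[s] = {
                "ppv": est.point,
                "ppv_pct": est.point_pct,
                "ci": [est.ci_low, est.ci_high],
            }
    report["ppv"] = ppvs

    yields = {}
    for target in ("ai", "ehr", "combined"):
        try:
            est = estimate_cohort_yield(table, target, config.n_boot, rng_boot)
        except GascreenError:
            continue
        yields[target] = {
            "estimated_eligible": est.count,
            "rate": est.rate,
            "rate_pct": est.rate_pct,
            "rate_ci": list(est.rate_ci),
            "shortlist_size": est.shortlist_size,
        }
    report["yield"] = yields
    report["improvement_ai_vs_ehr_pct"] = (
        percent(yields["ai"]["rate"] - yields["ehr"]["rate"])
        if "ai" in yields and "ehr" in yields
        else None
    )
    report["improvement_combined_vs_ehr_pct"] = (
        percent(yields["combined"]["rate"] - yields["ehr"]["rate"])
        if "combined" in yields and "ehr" in yields
        else None
    )

    # --- agreement: grader-averaged FAF area vs AI OCT area ----------------
    pairs = []
    grader_rows = []
    for p in patients:
        for lat, eye in p.eyes.items():
            g1 = [a for ll, g, a in p.faf_gradings if ll == lat and g == "grader_1"]
            g2 = [a for ll, g, a in p.faf_gradings if ll == lat and g == "grader_2"]
            if g1 and g2:
                avg = (g1[0] + g2[0]) / 2.0
                ai_area = profiles[(p.patient_id, lat)].area_mm2
                pairs.append(AgreementPair(avg, ai_area))
                grader_rows.append((g1[0], g2[0]))
    if len(pairs) >= 2:
        ba = bland_altman(pairs)
        report["bland_altman_faf_vs_ai"] = {
            "mean_diff_mm2": ba.mean_diff,
            "loa": [ba.loa_lower, ba.loa_upper],
            "n": ba.n,
        }
        mat = np.array([[a.measurement_a, a.measurement_b] for a in pairs])
        icc = icc_agreement(mat, n_boot=config.n_boot, rng=rng_boot)
        report["icc_faf_vs_ai"] = {"icc": icc.icc, "ci": [icc.ci_low, icc.ci_high]}
    if len(grader_rows) >= 2:
        gmat = np.array(grader_rows)
        icc_g = icc_agreement(gmat, n_boot=config.n_boot, rng=rng_boot)
        report["icc_intergrader"] = {
            "icc": icc_g.icc,
            "ci": [icc_g.ci_low, icc_g.ci_high],
        }

    # --- demographic comparison between the two shortlists -----------------
    ages_ai = [patients_by_id[pid].age_years for pid in ai_ids]
    ages_ehr = [patients_by_id[pid].age_years for pid in ehr_ids]
    if ages_ai and ages_ehr:
        report["age_compare_p"] = bootstrap_group_compare(
            ages_ai, ages_ehr, "mean", config.n_boot, rng_boot
        )

    # --- outputs ------------------------------------------------------------
    out_path = None
    if out is not None:
        gio.write_cohort(
            patients, ground_truth, geometry, out / "cohort",
            include_maps=config.write_maps,
        )
        gio.write_profiles_csv(profiles, out / "profiles.csv")
        gio.write_ehr_flags_csv(ehr_flags, out / "ehr_flags.csv")
        for (tid, mode), ids in shortlists.items():
            pd.DataFrame({"patient_id": ids}).to_csv(
                out / f"shortlist_{tid}_{mode}.csv", index=False
            )
        vt_rows = [
            {
                "stratum": s,
                "n_sampled": sm.n_sampled,
                "n_eligible": sm.n_eligible,
                "population": populations[s],
            }
            for s, sm in samples.items()
        ]
        pd.DataFrame(vt_rows).to_csv(out / "validation_table.csv", index=False)
        pd.DataFrame(
            [
                {"measurement_a": a.measurement_a, "measurement_b": a.measurement_b}
                for a in pairs
            ],
            columns=["measurement_a", "measurement_b"],
        ).to_csv(out / "agreement_pairs.csv", index=False)
        import json as _json

        (out / "report.json").write_text(_json.dumps(report, indent=2, sort_keys=True))
        gio.write_manifest(out, seed=master)
        out_path = out

    return PipelineResult(
        config=config,
        patients=patients,
        ground_truth=ground_truth,
        profiles=profiles,
        ehr_flags=ehr_flags,
        shortlists=shortlists,
        strata=strata,
        validation_table=table,
        report=report,
        out_dir=out_path,
    )
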