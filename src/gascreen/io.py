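"""Readers and writers for the on-disk cohort and result formats.

A cohort directory holds:

- ``patients.csv`` — one row per patient (demographics, inclusion flag);
- ``eyes/`` — per-eye maps in a plain-text dialect: ``<pid>_<lat>_rpe.txt``
  (0/1 integers, one B-scan per line), ``<pid>_<lat>_nsr.txt`` (thickness in
  micrometres, scientific notation), and a ``<pid>_<lat>_meta.json`` sidecar
  with dates, flags, planted truth and the value scales;
- ``letters.jsonl`` — one JSON object per clinic letter;
- ``gradings.csv`` — simulated FAF grader areas;
- ``ground_truth.csv`` — planted truth, one row per eye;
- ``geometry.json`` — the scan geometry shared by all maps.

Dates are ISO-8601 throughout; laterality is coded "L"/"R".  Every pipeline
run also writes a ``manifest.json`` recording the seed and SHA-256 digests
of all outputs, so reruns can be checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EyeRecord, PatientRecord
from .errors import DataError
from .geometry import ScanGeometry


def _iso(d: date | None) -> str | None:
    return None if d is None else d.isoformat()


def _from_iso(s) -> date | None:
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return None
    return date.fromisoformat(str(s))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def write_cohort(
    patients: list[PatientRecord],
    ground_truth: pd.DataFrame,
    geometry: ScanGeometry,
    out_dir: str | Path,
    include_maps: bool = True,
) -> Path:
    """Serialize a cohort to a directory; returns the directory path.

    ``include_maps=False`` skips the per-eye array files (the bulky part);
    everything else is always written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "geometry.json").write_text(json.dumps(geometry.to_dict(), indent=2))

    rows = [
        {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "ethnicity": p.ethnicity,
            "imd_decile": p.imd_decile,
            "passes_inclusion": p.passes_inclusion,
        }
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(out / "patients.csv", index=False)

    eyes_dir = out / "eyes"
    eyes_dir.mkdir(exist_ok=True)
    for p in patients:
        for lat, eye in sorted(p.eyes.items()):
            stem = f"{p.patient_id}_{lat}"
            meta = {
                "patient_id": p.patient_id,
                "laterality": lat,
                "ga_flag": eye.ga_flag,
                "cnv_flag": eye.cnv_flag,
                "drusen_flag": eye.drusen_flag,
                "oct_date": _iso(eye.oct_date),
                "faf_date": _iso(eye.faf_date),
                "true_fovea_px": list(eye.true_fovea_px),
                "true_area_mm2": eye.true_area_mm2,
                "rpe_scale": "0/1 integers; 1 = RPE present",
                "nsr_scale": "micrometres",
            }
            (eyes_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
            if include_maps:
                np.savetxt(
                    eyes_dir / f"{stem}_rpe.txt",
                    eye.rpe_present.astype(np.int8),
                    fmt="%d",
                )
                np.savetxt(
                    eyes_dir / f"{stem}_nsr.txt", eye.nsr_thickness, fmt="%.6e"
                )

    with (out / "letters.jsonl").open("w") as fh:
        for p in patients:
            for d, text in p.sorted_letters():
                fh.write(
                    json.dumps(
                        {"patient_id": p.patient_id, "date": _iso(d), "text": text}
                    )
                    + "\n"
                )

    grows = [
        {
            "patient_id": p.patient_id,
            "laterality": lat,
            "grader_id": gid,
            "area_mm2": area,
        }
        for p in patients
        for lat, gid, area in p.faf_gradings
    ]
    pd.DataFrame(
        grows, columns=["patient_id", "laterality", "grader_id", "area_mm2"]
    ).to_csv(out / "gradings.csv", index=False)

    ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def read_letters_jsonl(path: str | Path) -> dict[str, list[tuple[date, str]]]:
    """Parse letters.jsonl into per-patient (date, text) lists.

    Malformed lines raise :class:`DataError` citing the 1-based line number.
    """
    letters: dict[str, list[tuple[date, str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                pid = obj["patient_id"]
                entry = (date.fromisoformat(obj["date"]), obj["text"])
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
            letters.setdefault(pid, []).append(entry)
    return letters


def read_cohort(
    cohort_dir: str | Path, require_maps: bool = True
) -> tuple[list[PatientRecord], pd.DataFrame, ScanGeometry]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    try:
        geometry = ScanGeometry.from_dict(
            json.loads((root / "geometry.json").read_text())
        )
        pframe = pd.read_csv(root / "patients.csv")
        ground_truth = pd.read_csv(root / "ground_truth.csv")
    except FileNotFoundError as exc:
        raise DataError(f"not a cohort directory: {exc}") from exc

    letters = read_letters_jsonl(root / "letters.jsonl")
    gradings = pd.read_csv(root / "gradings.csv")

    patients: list[PatientRecord] = []
    eyes_dir = root / "eyes"
    for row in pframe.itertuples():
        p = PatientRecord(
            patient_id=str(row.patient_id),
            age_years=float(row.age_years),
            sex=str(row.sex),
            ethnicity=str(row.ethnicity),
            imd_decile=int(row.imd_decile),
            passes_inclusion=bool(row.passes_inclusion),
        )
        p.letters = letters.get(p.patient_id, [])
        sub = gradings[gradings.patient_id == p.patient_id]
        p.faf_gradings = [
            (r.laterality, r.grader_id, float(r.area_mm2)) for r in sub.itertuples()
        ]
        for meta_path in sorted(eyes_dir.glob(f"{p.patient_id}_*_meta.json")):
            meta = json.loads(meta_path.read_text())
            lat = meta["laterality"]
            stem = f"{p.patient_id}_{lat}"
            if require_maps:
                rpe = np.loadtxt(eyes_dir / f"{stem}_rpe.txt", dtype=np.int8).astype(
                    bool
                )
                nsr = np.loadtxt(eyes_dir / f"{stem}_nsr.txt", dtype=float)
                rpe = rpe.reshape(geometry.shape)
                nsr = nsr.reshape(geometry.shape)
            else:
                rpe = np.ones(geometry.shape, dtype=bool)
                nsr = np.zeros(geometry.shape, dtype=float)
            p.eyes[lat] = EyeRecord(
                laterality=lat,
                rpe_present=rpe,
                nsr_thickness=nsr,
                ga_flag=bool(meta["ga_flag"]),
                cnv_flag=bool(meta["cnv_flag"]),
                drusen_flag=bool(meta["drusen_flag"]),
                oct_date=_from_iso(meta["oct_date"]),
                faf_date=_from_iso(meta["faf_date"]),
                true_fovea_px=tuple(meta["true_fovea_px"]),
                true_area_mm2=float(meta["true_area_mm2"]),
            )
        patients.append(p)
    return patients, ground_truth, geometry


def cohort_digest(patients: list[PatientRecord]) -> str:
    """SHA-256 over a canonical serialization of the in-memory cohort.

    Used to assert seeded reproducibility without touching disk.
    """
    h = hashlib.sha256()
    for p in patients:
        h.update(
            f"{p.patient_id}|{p.age_years!r}|{p.sex}|{p.ethnicity}|{p.imd_decile}".encode()
        )
        for d, text in p.sorted_letters():
            h.update(f"{d.isoformat()}|{text}".encode())
        for lat, gid, area in p.faf_gradings:
            h.update(f"{lat}|{gid}|{area!r}".encode())
        for lat, eye in sorted(p.eyes.items()):
            h.update(
                f"{lat}|{eye.ga_flag}|{eye.cnv_flag}|{eye.drusen_flag}|"
                f"{eye.oct_date}|{eye.faf_date}|{eye.true_fovea_px}|"
                f"{eye.true_area_mm2!r}".encode()
            )
            h.update(np.packbits(eye.rpe_present).tobytes())
            h.update(eye.nsr_thickness.tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_profiles_csv(profiles: dict, path: str | Path) -> None:
    """Write per-eye imaging profiles: one row per (patient, laterality)."""
    rows = [
        {
            "patient_id": pid,
            "laterality": lat,
            "area_mm2": f"{prof.area_mm2:.4f}",
            "central_ga": prof.central_ga,
            "fovea_involving": prof.fovea_involving,
            "fovea_row": prof.fovea_px[0],
            "fovea_col": prof.fovea_px[1],
            "is_ga": prof.is_ga,
        }
        for (pid, lat), prof in sorted(profiles.items())
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "laterality",
            "area_mm2",
            "central_ga",
            "fovea_involving",
            "fovea_row",
            "fovea_col",
            "is_ga",
        ],
    ).to_csv(path, index=False)


def write_ehr_flags_csv(flags: dict, path: str | Path) -> None:
    rows = [
        {
            "patient_id": pid,
            "matched": f.matched,
            "earliest_date": _iso(f.earliest_date),
        }
        for pid, f in sorted(flags.items())
    ]
    pd.DataFrame(rows, columns=["patient_id", "matched", "earliest_date"]).to_csv(
        path, index=False
    )


def write_manifest(out_dir: str | Path, seed: int, extra: dict | None = None) -> Path:
    """Record the seed and SHA-256 digests of every file under ``out_dir``.

    Deliberately contains nothing run-dependent besides the outputs
    themselves (no timestamps), so identical reruns produce identical
    manifests.
    """
    out = Path(out_dir)
    digests = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            digests[str(f.relative_to(out))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    manifest = {"seed": seed, "files": digests}
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
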