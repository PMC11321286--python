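"""Area quantification, fovea localization and location classification."""

import numpy as np
import pytest

from gascreen import (
    CohortConfig,
    GeometryError,
    IncompleteRecordError,
    LesionSpec,
    ScanGeometry,
    classify_location,
    compute_ga_area,
    generate_cohort,
    locate_fovea,
    profile_eye,
    render_lesion,
)
from gascreen.cohort import _thickness_map


class TestComputeGaArea:
    def test_intact_rpe_gives_zero(self, geom):
        area, mask = compute_ga_area(np.ones(geom.shape, bool), geom)
        assert area == 0.0 and not mask.any()

    def test_full_field_absence(self, geom):
        area, _ = compute_ga_area(np.zeros(geom.shape, bool), geom)
        assert area == pytest.approx(36.0)

    def test_pixel_count_to_mm2_conversion(self, geom):
        # contiguous block of exactly 5243 absent pixels on the 512x128 grid
        # over 6x6 mm: 5243 * (6/512) * (6/128) = 2.88 mm^2 (3 s.f.)
        rpe = np.ones(geom.shape, bool)
        flat = rpe.reshape(-1)
        flat[:5243] = False
        area, _ = compute_ga_area(rpe, geom)
        assert area == pytest.approx(5243 * 36 / 65536)
        assert round(area, 2) == 2.88

    def test_speckle_filter_removes_small_components(self, geom):
        rpe = np.ones(geom.shape, bool)
        rpe[10, 10] = False  # single pixel << 0.05 mm^2
        area, mask = compute_ga_area(rpe, geom)
        assert area == 0.0 and not mask.any()
        # but kept when the filter is disabled
        area2, _ = compute_ga_area(rpe, geom, min_component_mm2=0.0)
        assert area2 == pytest.approx(geom.pixel_area_mm2)

    def test_dimension_mismatch_raises(self, geom):
        with pytest.raises(GeometryError):
            compute_ga_area(np.ones((10, 10), bool), geom)

    def test_area_monotone_in_absent_pixels(self, geom, rng):
        """Adding absent pixels never decreases the area."""
        spec = LesionSpec(shape="disc", target_area_mm2=4.0)
        mask = render_lesion(spec, geom, (64, 256))
        rpe = ~mask
        base, _ = compute_ga_area(rpe, geom)
        grown = mask | render_lesion(
            LesionSpec(shape="disc", target_area_mm2=1.0, center_mm=(1.5, 0)),
            geom,
            (64, 256),
        )
        bigger, _ = compute_ga_area(~grown, geom)
        assert bigger >= base


class TestLocateFovea:
    def test_recovers_planted_pit(self, geom, rng):
        cfg = CohortConfig(n_patients=1)
        t = _thickness_map(cfg, geom, (64, 256), rng)
        row, col = locate_fovea(t, geom)
        assert abs(row - 64) <= 3 and abs(col - 256) <= 3

    def test_constant_map_warns_and_returns_window_center(self, geom):
        with pytest.warns(RuntimeWarning):
            row, col = locate_fovea(np.full(geom.shape, 300.0), geom)
        assert (row, col) == (64, 256)

    def test_translation_shifts_recovered_fovea(self, geom, rng):
        cfg = CohortConfig(n_patients=1)
        shift_px = int(round(0.5 / geom.col_pitch_mm))
        t0 = _thickness_map(cfg, geom, (64, 256), rng)
        t1 = _thickness_map(cfg, geom, (64, 256 + shift_px), rng)
        _, c0 = locate_fovea(t0, geom)
        _, c1 = locate_fovea(t1, geom)
        assert abs((c1 - c0) - shift_px) <= 3

    def test_rejects_nonfinite(self, geom):
        t = np.full(geom.shape, 300.0)
        t[0, 0] = np.nan
        with pytest.raises(ValueError):
            locate_fovea(t, geom)


class TestClassifyLocation:
    def test_foveal_disc_is_central_and_involving(self, geom):
        mask = render_lesion(LesionSpec(target_area_mm2=3.0), geom, (64, 256))
        assert classify_location(mask, (64, 256), geom) == (True, True)

    def test_perifoveal_ring_is_central_not_involving(self, geom):
        # annulus from 0.8 to 1.2 mm: area = pi (1.2^2 - 0.8^2)
        spec = LesionSpec(
            shape="ring",
            target_area_mm2=np.pi * (1.2**2 - 0.8**2),
            inner_radius_mm=0.8,
        )
        mask = render_lesion(spec, geom, (64, 256))
        assert classify_location(mask, (64, 256), geom) == (True, False)

    def test_distant_lesion_is_neither(self, geom):
        # disc of radius 0.3 mm centred 2.0 mm away: nearest point 1.7 mm
        spec = LesionSpec(
            shape="disc", target_area_mm2=np.pi * 0.3**2, center_mm=(2.0, 0.0)
        )
        mask = render_lesion(spec, geom, (64, 256))
        assert classify_location(mask, (64, 256), geom) == (False, False)

    def test_empty_mask(self, geom):
        assert classify_location(np.zeros(geom.shape, bool), (64, 256), geom) == (
            False,
            False,
        )

    def test_agrees_with_exhaustive_check_small_grids(self):
        """Vectorized classification == brute-force per-pixel loop."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            nb = int(rng.integers(4, 33))
            na = int(rng.integers(4, 33))
            g = ScanGeometry(
                n_bscans=nb,
                n_ascans=na,
                width_mm=float(rng.uniform(2, 8)),
                height_mm=float(rng.uniform(2, 8)),
            )
            mask = rng.uniform(size=(nb, na)) < 0.15
            fovea = (int(rng.integers(0, nb)), int(rng.integers(0, na)))
            got = classify_location(mask, fovea, g)
            central = False
            for r in range(nb):
                for c in range(na):
                    if not mask[r, c]:
                        continue
                    d = np.hypot(
                        (r - fovea[0]) * g.row_pitch_mm,
                        (c - fovea[1]) * g.col_pitch_mm,
                    )
                    central = central or d <= 1.5
            assert got == (central, bool(mask[fovea]))

    def test_translation_equivariance(self, geom):
        """Translating mask and fovea together preserves area and flags."""
        spec = LesionSpec(shape="disc", target_area_mm2=2.0, center_mm=(0.9, 0.0))
        m0 = render_lesion(spec, geom, (64, 200))
        m1 = render_lesion(spec, geom, (64, 300))
        a0, _ = compute_ga_area(~m0, geom)
        a1, _ = compute_ga_area(~m1, geom)
        assert a0 == pytest.approx(a1, abs=2 * geom.pixel_area_mm2)
        assert classify_location(m0, (64, 200), geom) == classify_location(
            m1, (64, 300), geom
        )

    def test_fovea_outside_grid_rejected(self, geom):
        with pytest.raises(ValueError):
            classify_location(np.zeros(geom.shape, bool), (200, 0), geom)


class TestProfileEye:
    def _eye(self, geom, spec, rng, ga=True, misfix=(0, 0)):
        from gascreen.cohort import EyeRecord
        from datetime import date

        fovea = (64 + misfix[0], 256 + misfix[1])
        cfg = CohortConfig(n_patients=1)
        mask = render_lesion(spec, geom, fovea) if spec else np.zeros(geom.shape, bool)
        return EyeRecord(
            laterality="L",
            rpe_present=~mask,
            nsr_thickness=_thickness_map(cfg, geom, fovea, rng),
            ga_flag=ga,
            cnv_flag=False,
            drusen_flag=ga,
            oct_date=date(2020, 1, 1),
            faf_date=None,
            true_fovea_px=fovea,
            true_area_mm2=spec.target_area_mm2 if spec else 0.0,
        )

    def test_intact_eye_profile(self, geom, rng):
        prof = profile_eye(self._eye(geom, None, rng, ga=False), geom)
        assert prof.area_mm2 == 0.0
        assert (prof.central_ga, prof.fovea_involving) == (False, False)
        assert not prof.is_ga

    def test_foveal_disc_profile(self, geom, rng):
        spec = LesionSpec(shape="disc", target_area_mm2=3.0)
        eye = self._eye(geom, spec, rng)
        prof = profile_eye(eye, geom)
        assert prof.area_mm2 == pytest.approx(3.0, abs=0.15)
        assert prof.central_ga and prof.fovea_involving

    def test_extrafoveal_multifocal_not_central(self, geom, rng):
        # three small foci around a point 2.5 mm from the fovea; total extent
        # keeps every focus beyond the 1.5 mm central zone
        spec = LesionSpec(
            shape="multifocal", target_area_mm2=0.6, n_foci=3, center_mm=(2.3, 0.0)
        )
        eye = self._eye(geom, spec, rng)
        prof = profile_eye(eye, geom)
        assert prof.area_mm2 > 0
        assert not prof.central_ga and not prof.fovea_involving

    def test_missing_map_raises(self, geom, rng):
        eye = self._eye(geom, None, rng)
        eye.nsr_thickness = None
        with pytest.raises(IncompleteRecordError):
            profile_eye(eye, geom)


def test_parameter_recovery_over_seeded_eyes(horizon):
    """Measured area and fovea recover the planted truth across a cohort."""
    cfg = CohortConfig(n_patients=30, seed=11, misfixation_max_mm=0.0,
                       ga_prevalence=1.0)
    patients, gt = generate_cohort(cfg)
    geom = cfg.geometry
    errs, tols, fovea_hits, n = [], [], 0, 0
    truth = {(r.patient_id, r.laterality): r for r in gt.itertuples()}
    for p in patients:
        for lat, eye in p.eyes.items():
            prof = profile_eye(eye, geom)
            row = truth[(p.patient_id, lat)]
            from gascreen import rendering_tolerance_mm2

            errs.append(abs(prof.area_mm2 - row.true_area_mm2))
            tols.append(rendering_tolerance_mm2(~eye.rpe_present, geom))
            hit = (
                abs(prof.fovea_px[0] - row.fovea_row) <= 3
                and abs(prof.fovea_px[1] - row.fovea_col) <= 3
            )
            fovea_hits += hit
            n += 1
    assert np.mean(errs) <= 2 * np.mean(tols)
    assert fovea_hits / n >= 0.95
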