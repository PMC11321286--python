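"""Validation statistics: PPV, yield inference, ICC, Bland-Altman, bootstrap."""

from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pytest

from gascreen import (
    AgreementPair,
    CohortConfig,
    CoverageError,
    InsufficientDataError,
    InvalidConfigError,
    SampleShortfallError,
    StratumSample,
    UndefinedStatisticError,
    ValidationTable,
    assign_strata,
    bland_altman,
    bootstrap_group_compare,
    estimate_cohort_yield,
    faf_available,
    generate_cohort,
    icc_agreement,
    ppv,
    sample_for_validation,
)


class TestAssignStrata:
    def test_membership_rules(self):
        labels = assign_strata(ai_ids=["a", "b"], ehr_ids=["b", "c"])
        assert labels == {"a": "A2", "b": "A1", "c": "B1"}

    def test_disjoint_cover_on_50_patient_universe(self, rng):
        ids = [f"P{i:03d}" for i in range(50)]
        ai = {i for i in ids if rng.uniform() < 0.4}
        ehr = {i for i in ids if rng.uniform() < 0.4}
        labels = assign_strata(ai, ehr)
        assert set(labels) == ai | ehr
        assert all(
            (labels[i] == "A1") == (i in ai and i in ehr)
            and (labels[i] == "A2") == (i in ai and i not in ehr)
            and (labels[i] == "B1") == (i not in ai and i in ehr)
            for i in labels
        )


def _patient_with_offsets(pid, off_l, off_r):
    """Two-eyed patient whose FAF dates sit off_l/off_r days from the OCT."""
    from gascreen.cohort import EyeRecord, PatientRecord

    p = PatientRecord(
        patient_id=pid, age_years=70, sex="F", ethnicity="White", imd_decile=5
    )
    d0 = date(2020, 1, 1)
    for lat, off in (("L", off_l), ("R", off_r)):
        p.eyes[lat] = EyeRecord(
            laterality=lat,
            rpe_present=np.ones((4, 4), bool),
            nsr_thickness=np.zeros((4, 4)),
            ga_flag=False,
            cnv_flag=False,
            drusen_flag=False,
            oct_date=d0,
            faf_date=None if off is None else d0 + timedelta(days=off),
            true_fovea_px=(2, 2),
            true_area_mm2=0.0,
        )
    return p


class TestSampleForValidation:
    def test_window_boundary_inclusive_at_90(self):
        assert faf_available(_patient_with_offsets("a", 90, -90))
        assert not faf_available(_patient_with_offsets("b", 91, 0))
        assert not faf_available(_patient_with_offsets("c", 0, None))

    def test_seeded_sample_reproducible(self):
        members = [_patient_with_offsets(f"P{i}", 10, -10) for i in range(20)]
        a = sample_for_validation(members, 5, np.random.default_rng(3))
        b = sample_for_validation(members, 5, np.random.default_rng(3))
        assert a == b and len(a) == 5

    def test_shortfall_error(self):
        members = [_patient_with_offsets("P0", 100, 0)]  # filtered out
        with pytest.raises(SampleShortfallError):
            sample_for_validation(members, 1, np.random.default_rng(0))


class TestPPV:
    @pytest.mark.parametrize(
        "x,n,pct", [(84, 98, 86), (36, 75, 48), (7, 81, 9)]
    )
    def test_point_estimates_round_to_published_percentages(self, x, n, pct):
        est = ppv(StratumSample("A1", n_sampled=n, n_eligible=x),
                  rng=np.random.default_rng(0))
        assert est.point == pytest.approx(x / n)
        assert est.point_pct == pct

    def test_degenerate_zero_eligible(self):
        est = ppv(StratumSample("B1", 50, 0), rng=np.random.default_rng(0))
        assert est.point == 0.0 and est.ci_low == 0.0 and est.ci_high == 0.0

    def test_empty_sample_undefined(self):
        with pytest.raises(InvalidConfigError):
            StratumSample("A1", n_sampled=0, n_eligible=1)
        with pytest.raises(UndefinedStatisticError):
            ppv(StratumSample("A1", 0, 0))

    def test_ci_brackets_point_and_is_seeded(self):
        s = StratumSample("A1", 98, 84)
        a = ppv(s, rng=np.random.default_rng(5))
        b = ppv(s, rng=np.random.default_rng(5))
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.point <= a.ci_high


def _published_table():
    return ValidationTable(
        samples={
            "A1": StratumSample("A1", 98, 84),
            "A2": StratumSample("A2", 75, 36),
            "B1": StratumSample("B1", 81, 7),
        },
        populations={"A1": 703, "A2": 1817 - 703, "B1": 1729 - 703},
    )


class TestYieldInference:
    def test_weighted_sum_rates(self):
        table = _published_table()
        rng = np.random.default_rng(0)
        ai = estimate_cohort_yield(table, "ai", rng=rng)
        ehr = estimate_cohort_yield(table, "ehr", rng=rng)
        comb = estimate_cohort_yield(table, "combined", rng=rng)
        assert ai.shortlist_size == 1817
        assert ehr.shortlist_size == 1729
        assert comb.shortlist_size == 703
        assert (ai.rate_pct, ehr.rate_pct, comb.rate_pct) == (63, 40, 86)

    def test_saturated_ppv_returns_population(self):
        table = ValidationTable(
            samples={
                "A1": StratumSample("A1", 10, 10),
                "A2": StratumSample("A2", 10, 10),
            },
            populations={"A1": 100, "A2": 200},
        )
        est = estimate_cohort_yield(table, "ai", rng=np.random.default_rng(0))
        assert est.count == pytest.approx(300.0)
        assert est.rate == pytest.approx(1.0)

    def test_missing_stratum_raises_coverage_error(self):
        table = ValidationTable(
            samples={"A1": StratumSample("A1", 10, 5)}, populations={"A1": 50}
        )
        with pytest.raises(CoverageError):
            estimate_cohort_yield(table, "ai")

    def test_population_smaller_than_sample_rejected(self):
        with pytest.raises(InvalidConfigError):
            ValidationTable(
                samples={"A1": StratumSample("A1", 10, 5)}, populations={"A1": 5}
            )


class TestBlandAltman:
    def test_identical_pairs(self):
        pairs = [AgreementPair(3.0, 3.0)] * 5
        res = bland_altman(pairs)
        assert res.mean_diff == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)

    def test_constant_offset(self):
        pairs = [AgreementPair(a + 2.0, a) for a in (1.0, 4.0, 9.0)]
        res = bland_altman(pairs)
        assert res.mean_diff == pytest.approx(2.0)
        assert res.loa_lower == pytest.approx(2.0)
        assert res.loa_upper == pytest.approx(2.0)

    def test_hand_computed_sd(self):
        # differences {-1, 0, 1}: mean 0, sample sd exactly 1
        pairs = [AgreementPair(1.0, 2.0), AgreementPair(2.0, 2.0),
                 AgreementPair(3.0, 2.0)]
        res = bland_altman(pairs)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.loa_lower == pytest.approx(-1.96)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([AgreementPair(1.0, 1.0)])

    def test_limits_cover_about_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 2, size=1000)
        d = rng.normal(0.5, 1.2, size=1000)
        pairs = [AgreementPair(x, max(x - dd, 0.0)) for x, dd in zip(a, d)]
        res = bland_altman(pairs)
        diffs = np.array([p.measurement_a - p.measurement_b for p in pairs])
        inside = np.mean((diffs >= res.loa_lower) & (diffs <= res.loa_upper))
        assert 0.93 <= inside <= 0.97


def _icc_anova_oracle(x):
    """Direct two-way ANOVA mean squares, spelled out longhand."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc_agreement(x, n_boot=100, rng=np.random.default_rng(0))
        assert res.icc == pytest.approx(1.0)

    def test_large_bias_small_subject_variance_near_zero(self):
        # agreement (not consistency) form: a constant offset kills the ICC
        subj = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        x = np.column_stack([subj, subj + 5.0])
        res = icc_agreement(x, n_boot=100, rng=np.random.default_rng(0))
        assert res.icc < 0.01

    def test_four_subject_matrix_matches_hand_anova(self):
        x = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 4.0], [7.0, 8.0]])
        res = icc_agreement(x, n_boot=10, rng=np.random.default_rng(0))
        assert res.icc == pytest.approx(_icc_anova_oracle(x), abs=1e-9)

    def test_random_matrices_match_anova_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(5, 2, size=(10, 2)) + rng.normal(
                0, 1, size=(10, 1)
            )
            res = icc_agreement(x, n_boot=10, rng=np.random.default_rng(0))
            assert res.icc == pytest.approx(_icc_anova_oracle(x), abs=1e-9)

    def test_matches_pingouin_icc2(self):
        """Independent cross-check against pingouin's ICC2 on a random matrix."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        x = rng.normal(8, 3, size=(12, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        icc_table = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        row = icc_table.Type.isin(["ICC2", "ICC(A,1)"])
        expected = float(icc_table.loc[row, "ICC"].iloc[0])
        res = icc_agreement(x, n_boot=10, rng=np.random.default_rng(0))
        assert res.icc == pytest.approx(expected, abs=1e-9)

    def test_constant_ratings_degenerate(self):
        with pytest.warns(RuntimeWarning):
            res = icc_agreement(np.full((5, 2), 3.0), n_boot=10)
        assert res.icc == 0.0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(InsufficientDataError):
            icc_agreement(np.zeros((1, 2)))
        with pytest.raises(InsufficientDataError):
            icc_agreement(np.zeros((5, 1)))


class TestBootstrapGroupCompare:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200)
        p = bootstrap_group_compare(a, a.copy(), "mean", n_boot=2000,
                                    rng=np.random.default_rng(0))
        assert p > 0.5

    def test_separated_groups_p_below_resolution(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)
        n_boot = 2000
        p = bootstrap_group_compare(a, b, "mean", n_boot=n_boot,
                                    rng=np.random.default_rng(0))
        assert p <= 2 / n_boot

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.3, 1, 50)
        p1 = bootstrap_group_compare(a, b, rng=np.random.default_rng(7), n_boot=1000)
        p2 = bootstrap_group_compare(a, b, rng=np.random.default_rng(7), n_boot=1000)
        assert p1 == p2

    def test_proportion_statistic_validates_input(self):
        with pytest.raises(InvalidConfigError):
            bootstrap_group_compare([0.5, 1.0], [0, 1], "proportion")
        p = bootstrap_group_compare(
            [0, 1, 1, 0] * 25, [1, 1, 1, 0] * 25, "proportion",
            n_boot=1000, rng=np.random.default_rng(0),
        )
        assert 0.0 < p <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_group_compare([], [1.0])


def test_census_closure_on_synthetic_cohort(horizon):
    """Sampling entire strata makes the inferred count exactly the truth."""
    from gascreen import PipelineConfig, run_pipeline

    cfg = PipelineConfig(
        cohort=CohortConfig(
            n_patients=80, faf_missing_prob=0.0, faf_offset_max_days=60
        ),
        criteria=[horizon],
        seed=29,
        validation_n=None,  # census
        n_boot=200,
    )
    res = run_pipeline(cfg)
    col = f"patient_eligible_{horizon.trial_id}"
    eligible = set(res.ground_truth.loc[res.ground_truth[col], "patient_id"])
    for target in ("ai", "ehr", "combined"):
        if target not in res.report["yield"]:
            continue
        covered = {
            "ai": {"A1", "A2"}, "ehr": {"A1", "B1"}, "combined": {"A1"}
        }[target]
        truth = sum(
            1 for pid, s in res.strata.items() if s in covered and pid in eligible
        )
        assert res.report["yield"][target]["estimated_eligible"] == pytest.approx(
            truth
        )
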