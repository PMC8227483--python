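"""Segmentation, organ dose reduction, effective dose, cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from perfdose import dose_report as dr
from perfdose import synthetic_data as sd
from perfdose.mc_transport import DoseGrid
from perfdose.voxel_io import VoxelVolume


def dose_grid(values, spacing=(1, 1, 1)):
    return DoseGrid(VoxelVolume(np.asarray(values, float), spacing, role="dose"))


class TestSegmentHu:
    def test_full_window_returns_roi(self, patient_case):
        hu, _ = patient_case
        roi = np.ones(hu.shape, bool)
        mask = dr.segment_hu(hu, roi, -1024, 3071)
        assert np.array_equal(mask, roi)

    def test_noise_free_lung_window_recovers_truth(self, patient_case):
        hu, truth = patient_case
        ids = {n: l for l, n in truth.meta["label_map"].items()}
        lung_truth = np.isin(truth.values, [ids["lung_left"], ids["lung_right"]])
        mask = dr.segment_hu(hu, np.ones(hu.shape, bool), -899, -300)
        assert np.array_equal(mask, lung_truth)

    def test_disjoint_window_warns_and_is_empty(self, patient_case):
        hu, _ = patient_case
        with pytest.warns(UserWarning, match="empty"):
            mask = dr.segment_hu(hu, np.ones(hu.shape, bool), 3000, 3071)
        assert not mask.any()

    def test_empty_roi_errors(self, patient_case):
        hu, _ = patient_case
        with pytest.raises(ValueError, match="region of interest"):
            dr.segment_hu(hu, np.zeros(hu.shape, bool), -100, 100)


class TestOrganMeanDose:
    def test_uniform_grid(self):
        grid = dose_grid(np.full((4, 4, 4), 5.0))
        assert dr.organ_mean_dose(grid, np.ones((4, 4, 4), bool)) == 5.0

    def test_two_voxel_mean(self):
        vals = np.zeros((2, 1, 1))
        vals[0, 0, 0], vals[1, 0, 0] = 2.0, 4.0
        assert dr.organ_mean_dose(dose_grid(vals), np.ones((2, 1, 1), bool)) == 3.0

    def test_checkerboard_half(self):
        vals = np.indices((4, 4, 4)).sum(axis=0) % 2
        assert dr.organ_mean_dose(dose_grid(vals), np.ones((4, 4, 4), bool)) == 0.5

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dr.organ_mean_dose(dose_grid(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool))


class TestRbmDose:
    def test_meac_conversion_patient_only(self):
        assert dr.rbm_dose(10.0, 100, 0.0, 0, 0.2761) == pytest.approx(2.761)

    def test_phantom_only_degenerate(self):
        assert dr.rbm_dose(0.0, 0, 4.0, 50, 0.2761) == pytest.approx(4.0)

    def test_equal_counts_weighted_mean(self):
        # patient term contributes 2 mGy after the ratio, phantom 4 mGy
        got = dr.rbm_dose(2.0 / 0.5, 10, 4.0, 10, 0.5, spongiosa_fraction=1.0)
        assert got == pytest.approx(3.0)

    def test_bounded_between_component_terms(self, rng):
        for _ in range(50):
            d_b, d_s = rng.uniform(0.1, 10, 2)
            n_b, n_s = rng.integers(1, 500, 2)
            ratio = rng.uniform(0.1, 0.9)
            frac = rng.uniform(0.1, 1.0)
            out = dr.rbm_dose(d_b, int(n_b), d_s, int(n_s), ratio, frac)
            lo = min(ratio * d_b, d_s)
            hi = max(ratio * d_b, d_s)
            assert lo - 1e-12 <= out <= hi + 1e-12

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            dr.rbm_dose(1.0, 0, 1.0, 0, 0.3)


class TestEffectiveDose:
    @pytest.fixture()
    def weights(self):
        return dr.load_icrp103_female_weights()

    def test_weights_sum_to_one(self, weights):
        total = sum(weights.weights.values()) + weights.remainder_weight
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_uniform_dose_is_normalisation_check(self, weights):
        doses = {o: 3.7 for o in list(weights.weights) + weights.remainder}
        assert dr.effective_dose(doses, weights) == pytest.approx(3.7)

    def test_breast_only_single_term(self, weights):
        doses = {o: 0.0 for o in list(weights.weights) + weights.remainder}
        doses["breasts"] = 10.0
        assert dr.effective_dose(doses, weights) == pytest.approx(1.2)

    def test_missing_organ_errors_with_names(self):
        w = dr.TissueWeights({"a": 0.5, "b": 0.5}, [], 0.0)
        with pytest.raises(KeyError, match="b"):
            dr.effective_dose({"a": 2.0}, w)


class TestLymphFallback:
    def test_phantom_constant_applied(self):
        cohort = dr.load_reference_cohort(80)
        phantom = next(r for r in cohort if r.case_id == "ICRP")
        assert dr.lymph_fallback(phantom) == pytest.approx(3.88)
        for r in cohort:
            assert r.doses["lymphatic_nodes"] == pytest.approx(3.88)

    def test_100kv_constant(self):
        cohort = dr.load_reference_cohort(100)
        assert dr.lymph_fallback(cohort[-1]) == pytest.approx(6.91)

    def test_missing_run_errors(self):
        with pytest.raises(ValueError, match="phantom"):
            dr.lymph_fallback(None)


def patients_only(cohort):
    return [r for r in cohort if r.case_id != "ICRP"]


SELECTED_80 = {"1", "3", "4", "5", "6", "7", "8", "9", "10", "12", "14", "15", "18"}


class TestCohortStatistics:
    def test_mean_effective_dose_80kv_all(self):
        reports = patients_only(dr.load_reference_cohort(80))
        summary = dr.cohort_statistics(reports)
        row = summary[(summary["group"] == "all") & (summary["quantity"] == "effective_dose")]
        assert float(row["mean"].iloc[0]) == pytest.approx(7.5, abs=0.05)

    def test_table6_group_means_and_sds(self):
        reports80 = patients_only(dr.load_reference_cohort(80))
        reports100 = patients_only(dr.load_reference_cohort(100))
        groups80 = {r.case_id: ("sel" if r.case_id in SELECTED_80 else "other")
                    for r in reports80}
        groups100 = {r.case_id: ("sel" if r.case_id not in SELECTED_80 else "other")
                     for r in reports100}
        s80 = dr.cohort_statistics(reports80, groups80)
        s100 = dr.cohort_statistics(reports100, groups100)
        expected = {  # (frame, group, quantity): (mean, sd)
            (0, "sel", "effective_dose"): (8.2, 2.1),
            (1, "sel", "effective_dose"): (11.1, 2.2),
            (0, "sel", "heart"): (35.3, 6.4),
            (1, "sel", "heart"): (46.0, 9.3),
            (0, "sel", "lungs"): (26.1, 4.3),
            (0, "sel", "breasts"): (23.8, 14.2),
            (1, "sel", "rbm"): (5.5, 0.5),
        }
        frames = [s80, s100]
        for (fi, g, q), (m, sdev) in expected.items():
            row = frames[fi][(frames[fi]["group"] == g) & (frames[fi]["quantity"] == q)]
            assert float(row["mean"].iloc[0]) == pytest.approx(m, abs=0.05), q
            assert float(row["sd"].iloc[0]) == pytest.approx(sdev, abs=0.05), q

    def test_all_patient_contrast_is_75_percent(self):
        r80 = patients_only(dr.load_reference_cohort(80))
        r100 = patients_only(dr.load_reference_cohort(100))
        groups = {**{r.case_id: "kv80" for r in r80}}
        s = dr.cohort_statistics(
            r80 + [dr.DoseReport(r.case_id + "_100", 100, r.doses,
                                 r.effective_dose_msv) for r in r100],
            {**groups, **{r.case_id + "_100": "kv100" for r in r100}})
        contrast = dr.group_contrast(s, "kv100", "kv80")
        assert contrast == pytest.approx(75.0, abs=1.0)

    def test_selected_group_contrast_is_36_percent(self):
        r80 = [r for r in patients_only(dr.load_reference_cohort(80))
               if r.case_id in SELECTED_80]
        r100 = [r for r in patients_only(dr.load_reference_cohort(100))
                if r.case_id not in SELECTED_80]
        e80 = np.mean([r.effective_dose_msv for r in r80])
        e100 = np.mean([r.effective_dose_msv for r in r100])
        assert 100 * (e100 - e80) / e80 == pytest.approx(36.0, abs=1.0)

    def test_combined_selected_mean_is_9_2(self):
        r80 = [r for r in patients_only(dr.load_reference_cohort(80))
               if r.case_id in SELECTED_80]
        r100 = [r for r in patients_only(dr.load_reference_cohort(100))
                if r.case_id not in SELECTED_80]
        combined = [r.effective_dose_msv for r in r80 + r100]
        assert np.mean(combined) == pytest.approx(9.2, abs=0.05)
        assert np.std(combined, ddof=1) == pytest.approx(2.5, abs=0.05)

    def test_two_equal_reports_sd_zero(self):
        r = dr.DoseReport("a", 80, {"heart": 2.0}, 2.0)
        r2 = dr.DoseReport("b", 80, {"heart": 2.0}, 2.0)
        s = dr.cohort_statistics([r, r2])
        assert float(s[s["quantity"] == "heart"]["sd"].iloc[0]) == 0.0

    def test_singleton_group_sd_blank(self):
        r = dr.DoseReport("a", 80, {"heart": 2.0}, 2.0)
        s = dr.cohort_statistics([r])
        assert np.isnan(float(s[s["quantity"] == "heart"]["sd"].iloc[0]))

    def test_unknown_group_label_errors(self):
        r = dr.DoseReport("a", 80, {"heart": 2.0}, 2.0)
        with pytest.raises(KeyError, match="group"):
            dr.cohort_statistics([r], {"someone_else": "g"})


class TestReportRoundTrip:
    def test_json_round_trip_preserves_effective_dose(self, tmp_path):
        weights = dr.load_icrp103_female_weights()
        rng = np.random.default_rng(0)
        doses = {o: float(rng.uniform(0.1, 30))
                 for o in list(weights.weights) + weights.remainder}
        e = dr.effective_dose(doses, weights)
        report = dr.DoseReport("p1", 80, doses, e, 313.0)
        path = tmp_path / "report.json"
        report.to_json(path)
        back = dr.DoseReport.from_json(path)
        assert back.doses == doses
        assert dr.effective_dose(back.doses, weights) == pytest.approx(
            back.effective_dose_msv, abs=1e-9)
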