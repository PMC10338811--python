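"""DVH endpoints, homogeneity/conformity indices, plan normalization and
plan differences."""

import numpy as np
import pytest

from contourdose import (DoseGrid, Mask, VoxelGrid, conformity_index,
                         cumulative_dvh, dose_at_volume, dose_differences,
                         evaluate_roi, homogeneity_index,
                         normalize_to_coverage, volume_at_dose)
from contourdose.dvh import oar_dose_differences, ptv_dose_differences
from contourdose.errors import (NormalizationError, UndefinedMetricError)

from conftest import dx_bracket, make_mask, scan_dx_exact


def grid_and_roi(shape=(4, 5, 5)):
    g = VoxelGrid(shape, (1.0, 1.0, 1.0))
    occ = np.ones(shape, dtype=bool)
    return g, Mask(g, occ, "roi")


def dose_from_values(values, shape=(4, 5, 5)):
    g = VoxelGrid(shape, (1.0, 1.0, 1.0))
    return DoseGrid(g, np.asarray(values, float).reshape(shape))


class TestCumulativeDVH:
    def test_uniform_dose_is_a_step(self):
        g, roi = grid_and_roi()
        dvh = cumulative_dvh(DoseGrid(g, np.full(g.dims, 50.0)), roi,
                             bin_width_gy=1.0)
        below = dvh.dose_edges_gy <= 50.0
        assert np.all(dvh.cumulative_volume_pct[below] == 100.0)
        assert np.all(dvh.cumulative_volume_pct[~below] == 0.0)

    def test_two_level_dose_splits_half(self):
        g = VoxelGrid((1, 1, 2), (1, 1, 1))
        roi = Mask(g, np.ones((1, 1, 2), bool), "r")
        dvh = cumulative_dvh(DoseGrid(g, np.array([[[40.0, 60.0]]])), roi,
                             bin_width_gy=1.0)
        mid = (dvh.dose_edges_gy > 40) & (dvh.dose_edges_gy <= 60)
        assert np.all(dvh.cumulative_volume_pct[mid] == 50.0)

    def test_curve_is_non_increasing_and_starts_at_100(self, rng):
        g, roi = grid_and_roi()
        dvh = cumulative_dvh(DoseGrid(g, rng.random(g.dims) * 60), roi)
        assert dvh.cumulative_volume_pct[0] == 100.0
        assert np.all(np.diff(dvh.cumulative_volume_pct) <= 0)

    def test_binned_curve_agrees_with_exact_endpoints(self, rng):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, rng.random(g.dims) * 60)
        bw = 0.01
        dvh = cumulative_dvh(dose, roi, bin_width_gy=bw)
        for x in (95.0, 50.0, 5.0):
            step_dx = scan_dx_exact(dose.dose.ravel(), x)
            # last edge still covering >= x% of the volume
            covered = dvh.dose_edges_gy[dvh.cumulative_volume_pct >= x]
            assert step_dx - bw < covered.max() <= step_dx + 1e-12


class TestDoseAtVolume:
    def test_uniform_dose(self):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, np.full(g.dims, 50.0))
        assert dose_at_volume(dose, roi, 95) == 50.0
        assert dose_at_volume(dose, roi, 5) == 50.0

    def test_interpolates_between_order_statistics(self):
        dose = dose_from_values(np.arange(1.0, 101.0), shape=(4, 5, 5))
        g, roi = grid_and_roi()
        d95 = dose_at_volume(dose, roi, 95)
        assert 5.0 < d95 < 6.0  # between the bracketing observed doses

    def test_matches_scan_counting_oracle(self, rng):
        g, roi = grid_and_roi()
        for _ in range(25):
            dose = DoseGrid(g, rng.random(g.dims) * 60)
            for x in rng.uniform(1, 100, size=3):
                r = dose_at_volume(dose, roi, x)
                lo, hi = dx_bracket(dose.dose.ravel(), x)
                assert lo - 1e-12 <= r <= hi + 1e-12

    def test_monotone_in_x(self, rng):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, rng.random(g.dims) * 60)
        assert dose_at_volume(dose, roi, 5) >= dose_at_volume(dose, roi, 95)

    def test_domain_errors(self):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, np.full(g.dims, 1.0))
        with pytest.raises(ValueError):
            dose_at_volume(dose, roi, 0)
        with pytest.raises(UndefinedMetricError):
            dose_at_volume(dose, make_mask([], shape=g.dims), 95)


class TestVolumeAtDose:
    def test_zero_threshold_is_everything(self):
        g, roi = grid_and_roi()
        assert volume_at_dose(DoseGrid(g, np.full(g.dims, 50.0)), roi, 0) == 100.0

    def test_above_everything_is_zero(self):
        g, roi = grid_and_roi()
        assert volume_at_dose(DoseGrid(g, np.full(g.dims, 50.0)), roi, 60) == 0.0

    def test_two_voxel_split(self):
        g = VoxelGrid((1, 1, 2), (1, 1, 1))
        roi = Mask(g, np.ones((1, 1, 2), bool), "r")
        dose = DoseGrid(g, np.array([[[40.0, 60.0]]]))
        assert volume_at_dose(dose, roi, 50) == 50.0


class TestIndices:
    def test_uniform_dose_has_unit_hi(self):
        g, roi = grid_and_roi()
        assert homogeneity_index(DoseGrid(g, np.full(g.dims, 50.0)), roi) == 1.0

    def test_two_level_hi(self):
        # 90% of voxels at 50 Gy, hottest 10% at 55 Gy -> D5 = 55, D95 = 50
        vals = np.full(100, 50.0)
        vals[:10] = 55.0
        g, roi = grid_and_roi()
        hi = homogeneity_index(dose_from_values(vals), roi)
        assert hi == pytest.approx(1.1, rel=1e-3)

    def test_hi_at_least_one(self, rng):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, rng.random(g.dims) * 60)
        assert homogeneity_index(dose, roi) >= 1.0

    def test_ci_perfect_conformity(self):
        g = VoxelGrid((4, 4, 4), (1, 1, 1))
        occ = np.zeros(g.dims, bool); occ[1:3, 1:3, 1:3] = True
        dose = np.where(occ, 50.0, 10.0)
        assert conformity_index(DoseGrid(g, dose), Mask(g, occ, "t"), 50.0) == 1.0

    def test_ci_hand_counted_nested_regions(self):
        # V_T = 100, V_dose = 200, V_R = 80 -> CI = 80*80/(100*200) = 0.32
        g = VoxelGrid((4, 10, 10), (1, 1, 1))
        target = np.zeros(g.dims, bool); target[0] = True            # 100
        dose = np.zeros(g.dims)
        dose[0, :8, :] = 60.0                                        # V_R = 80
        dose[1] = 60.0; dose[2, :2, :] = 60.0                        # +120 outside
        ci = conformity_index(DoseGrid(g, dose), Mask(g, target, "t"), 50.0)
        assert ci == pytest.approx(0.32)

    def test_ci_zero_when_target_misses_reference_dose(self):
        g = VoxelGrid((2, 2, 2), (1, 1, 1))
        target = np.zeros(g.dims, bool); target[0, 0, 0] = True
        dose = np.zeros(g.dims); dose[1, 1, 1] = 60.0
        assert conformity_index(DoseGrid(g, dose), Mask(g, target, "t"), 50.0) == 0.0

    def test_ci_undefined_without_reference_isodose(self):
        g, roi = grid_and_roi()
        with pytest.raises(UndefinedMetricError):
            conformity_index(DoseGrid(g, np.full(g.dims, 10.0)), roi, 50.0)

    def test_scaling_scales_dx_but_not_hi(self, rng):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, rng.random(g.dims) * 60 + 1)
        k = 2.5
        scaled = dose.scaled(k)
        for x in (5, 50, 95):
            assert dose_at_volume(scaled, roi, x) == pytest.approx(
                k * dose_at_volume(dose, roi, x), rel=1e-12)
        assert homogeneity_index(scaled, roi) == pytest.approx(
            homogeneity_index(dose, roi), rel=1e-12)


class TestNormalization:
    def test_already_normalized_is_unchanged(self):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, np.full(g.dims, 50.0))
        out = normalize_to_coverage(dose, roi, 50.0)
        np.testing.assert_allclose(out.dose, dose.dose)

    def test_uniform_scaling(self):
        g, roi = grid_and_roi()
        out = normalize_to_coverage(DoseGrid(g, np.full(g.dims, 25.0)), roi, 50.0)
        np.testing.assert_allclose(out.dose, 50.0)

    def test_post_normalization_d95_is_prescription(self, rng):
        g, roi = grid_and_roi()
        dose = DoseGrid(g, rng.random(g.dims) * 60 + 5)
        out = normalize_to_coverage(dose, roi, 50.0)
        assert dose_at_volume(out, roi, 95) == pytest.approx(50.0, rel=1e-9)

    def test_zero_d95_is_an_error(self):
        g, roi = grid_and_roi()
        with pytest.raises(NormalizationError):
            normalize_to_coverage(DoseGrid(g, np.zeros(g.dims)), roi, 50.0)


class TestEvaluateRoi:
    def test_ideal_target_plan(self):
        g = VoxelGrid((4, 4, 4), (1, 1, 1))
        occ = np.zeros(g.dims, bool); occ[1:3, 1:3, 1:3] = True
        dose = DoseGrid(g, np.where(occ, 50.0, 0.0))
        m = evaluate_roi(dose, Mask(g, occ, "PTV"), "target", 50.0)
        assert m.d_mean_gy == m.d_max_gy == m.d_min_gy == 50.0
        assert m.hi == 1.0 and m.ci == 1.0

    def test_spinal_cord_constraint_satisfied_at_44gy(self):
        g, _ = grid_and_roi()
        roi = Mask(g, np.ones(g.dims, bool), "SpinalCord")
        vals = np.full(100, 20.0); vals[0] = 44.0
        m = evaluate_roi(dose_from_values(vals), roi, "oar", 50.0)
        assert m.constraints["Dmax < 45 Gy"] is True

    def test_lung_v5_constraint_violated_at_70pct(self):
        g, _ = grid_and_roi()
        roi = Mask(g, np.ones(g.dims, bool), "Lung")
        vals = np.full(100, 1.0); vals[:70] = 6.0
        m = evaluate_roi(dose_from_values(vals), roi, "oar", 50.0)
        assert m.v_at[5.0] == pytest.approx(70.0)
        assert m.constraints["V5 < 60%"] is False
        assert m.constraints["V20 < 35%"] is True

    def test_dmin_dmean_dmax_ordering(self, rng):
        g, roi = grid_and_roi()
        m = evaluate_roi(DoseGrid(g, rng.random(g.dims) * 60), roi, "oar", 50.0)
        assert m.d_min_gy <= m.d_mean_gy <= m.d_max_gy


class TestDoseDifferences:
    def _case(self, shift_gy=0.0):
        from contourdose import Case, StructureSet
        g = VoxelGrid((6, 8, 8), (1, 1, 1))
        occ = np.zeros(g.dims, bool); occ[2:4, 2:6, 2:6] = True
        ptv = Mask(g, occ, "PTV")
        heart = Mask(g, np.roll(occ, 3, axis=1), "Heart")
        rng = np.random.default_rng(5)
        base = rng.random(g.dims) * 20 + 40
        manual = StructureSet(g, {"PTV": ptv, "Heart": heart}, "manual")
        auto = StructureSet(g, {"PTV": ptv}, "auto")
        return Case("c", manual, auto, DoseGrid(g, base),
                    DoseGrid(g, base + shift_gy), 50.0)

    def test_identical_plans_have_zero_deltas(self):
        diffs = dose_differences(self._case(0.0))
        for roi in diffs.values():
            for vals in roi.values():
                assert vals["delta"] == 0.0

    def test_uniform_shift_moves_dmean_exactly(self):
        diffs = dose_differences(self._case(1.0))
        assert diffs["PTV"]["d_mean"]["delta"] == pytest.approx(1.0, abs=1e-12)
        assert diffs["Heart"]["d_mean"]["delta"] == pytest.approx(1.0, abs=1e-12)
        # a uniform shift changes the D5/D95 ratio, so HI moves too
        assert diffs["PTV"]["hi"]["delta"] != 0.0

    def test_antisymmetric_under_plan_swap(self):
        case = self._case(1.0)
        from contourdose import Case
        swapped = Case(case.case_id, case.manual, case.auto,
                       case.dose_auto, case.dose_manual, case.prescription_gy)
        d1 = dose_differences(case)
        d2 = dose_differences(swapped)
        for roi in d1:
            for metric in d1[roi]:
                assert d2[roi][metric]["delta"] == pytest.approx(
                    -d1[roi][metric]["delta"], abs=1e-9)

    def test_helpers_cover_target_and_oar_blocks(self):
        case = self._case(1.0)
        assert set(ptv_dose_differences(case)) == {"d_mean", "d_max", "d_min",
                                                   "hi", "ci"}
        assert set(oar_dose_differences(case, "Heart")) == {"d_mean"}
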