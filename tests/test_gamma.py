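"""Gamma engine: closed-form cases, oracle checks, criteria monotonicity."""

import numpy as np
import pytest

from virtualqa import (
    DoseGrid,
    ErrorModel,
    GammaCriteria,
    GammaResult,
    brute_force_gamma_point,
    gamma_diode_2d,
    gamma_points,
    gamma_roi_3d,
    make_grid,
    passing_rate,
    simulate_measurement,
)
from virtualqa.gamma import grid_reference, local_curvature, surface_reference


def interior_points(n=50, lo=-30, hi=30, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, 3))


class TestCriteria:
    def test_must_be_positive(self):
        with pytest.raises(ValueError):
            GammaCriteria(0, 3)

    def test_fine_step_above_dta_refused(self):
        ref = DoseGrid(make_grid((40, 40, 40), (2, 2, 2)),
                       np.full((20, 20, 20), 10.0))
        with pytest.raises(ValueError, match="undersample"):
            gamma_points(np.zeros((1, 3)), np.array([10.0]), grid_reference(ref),
                         GammaCriteria(3, 3), norm_dose=10.0, fine_step_mm=4.0)


class TestClosedFormCases:
    def test_identical_fields_give_zero(self, smooth_fields):
        ref, _ = smooth_fields
        pts = interior_points()
        doses = ref.sample(pts)
        res = gamma_points(pts, doses, grid_reference(ref), GammaCriteria(3, 3),
                           norm_dose=ref.max)
        np.testing.assert_allclose(res.gamma, 0.0, atol=1e-9)
        assert res.passing_rate == 100.0

    def test_flat_field_two_percent_offset(self):
        g = make_grid((100, 100, 100), (2, 2, 2))
        ref = DoseGrid(g, np.full(g.shape, 50.0))
        pts = interior_points()
        res = gamma_points(pts, np.full(len(pts), 1.02 * 50.0),
                           grid_reference(ref), GammaCriteria(3, 3), norm_dose=50.0)
        np.testing.assert_allclose(res.gamma, 2.0 / 3.0, atol=1e-9)

    def test_linear_ramp_shift_bounded_by_dta(self):
        g = make_grid((100, 100, 100), (2, 2, 2))
        ax, _, _ = g.axes()
        vals = np.broadcast_to(ax[:, None, None] + 100.0, g.shape).copy()
        ref = DoseGrid(g, vals)
        pts = interior_points()
        shifted = pts + np.array([2.0, 0.0, 0.0])
        doses = ref.sample(shifted)
        res = gamma_points(pts, doses, grid_reference(ref), GammaCriteria(3, 3),
                           norm_dose=ref.max)
        assert np.all(res.gamma <= 2.0 / 3.0 + 1e-6)


class TestPassingRate:
    def _result(self, gammas, evaluable=None):
        gam = np.asarray(gammas, dtype=float)
        ev = np.ones_like(gam, bool) if evaluable is None else np.asarray(evaluable)
        return GammaResult(gamma=gam, evaluable=ev,
                           criteria=GammaCriteria(3, 3), norm_dose=100.0)

    def test_half_pass(self):
        assert passing_rate(self._result([1.5, 1.5, 0.5, 0.5])) == 50.0

    def test_boundary_gamma_one_passes(self):
        assert passing_rate(self._result([1.0, 1.0, 1.0])) == 100.0

    def test_only_evaluable_counted(self):
        res = self._result([2.0, 0.1], evaluable=[False, True])
        assert passing_rate(res) == 100.0

    def test_empty_region_is_error(self):
        res = self._result([0.5], evaluable=[False])
        with pytest.raises(ValueError, match="evaluable"):
            passing_rate(res)


class TestThreshold:
    def test_lower_threshold_never_decreases_evaluable(self, smooth_fields):
        ref, evl = smooth_fields
        pts = interior_points()
        doses = evl.sample(pts)
        counts = []
        for thr in (20.0, 10.0, 5.0):
            res = gamma_points(pts, doses, grid_reference(ref),
                               GammaCriteria(3, 3, threshold_pct=thr),
                               norm_dose=ref.max)
            counts.append(res.n_evaluable)
        assert counts == sorted(counts)


class TestOracleEquivalence:
    def test_engine_matches_dense_scan_on_shared_lattice(self, smooth_fields):
        ref, evl = smooth_fields
        pts = interior_points(n=60, seed=3)
        doses = evl.sample(pts)
        fn = grid_reference(ref)
        for crit in (GammaCriteria(3, 3), GammaCriteria(2, 2)):
            res = gamma_points(pts, doses, fn, crit, norm_dose=ref.max,
                               refine_levels=0)
            oracle = np.array([
                brute_force_gamma_point(p, d, fn, crit, ref.max,
                                        3 * crit.dta_mm, crit.dta_mm / 3.0)
                for p, d in zip(pts, doses)
            ])
            np.testing.assert_allclose(res.gamma, oracle, atol=1e-12)

    def test_refinement_only_improves(self, smooth_fields):
        ref, evl = smooth_fields
        pts = interior_points(n=60, seed=4)
        doses = evl.sample(pts)
        fn = grid_reference(ref)
        crit = GammaCriteria(3, 3)
        coarse = gamma_points(pts, doses, fn, crit, norm_dose=ref.max,
                              refine_levels=0).gamma
        fine = gamma_points(pts, doses, fn, crit, norm_dose=ref.max,
                            refine_levels=3).gamma
        assert np.all(fine <= coarse + 1e-12)


class TestCriteriaMonotonicity:
    def test_loosening_never_decreases_pass_status(self, smooth_fields):
        ref, evl = smooth_fields
        pts = interior_points(n=100, seed=5)
        doses = evl.sample(pts)
        fn = grid_reference(ref)
        g33 = gamma_points(pts, doses, fn, GammaCriteria(3, 3), norm_dose=ref.max)
        g22 = gamma_points(pts, doses, fn, GammaCriteria(2, 2), norm_dose=ref.max)
        passes33 = g33.gamma <= 1.0
        passes22 = g22.gamma <= 1.0
        assert np.all(passes33 | ~passes22)


class TestDiodeSurfaceGamma:
    def test_clean_measurement_passes_everywhere(self, case50):
        m = simulate_measurement(case50["planned"], case50["plan"], ErrorModel())[0]
        res = gamma_diode_2d(m, case50["planned"], case50["plan"].total_dose,
                             GammaCriteria(3, 3))
        assert res.passing_rate == 100.0
        assert res.gamma[res.evaluable].max() < 1e-6

    def test_surface_reference_matches_planned_reading(self, case50, geometry):
        fn = surface_reference(case50["plan"].total_dose, geometry)
        vals = fn(geometry.unwrapped())
        np.testing.assert_allclose(vals, case50["planned"].composite, rtol=1e-9)

    def test_angular_wrap_is_periodic(self, case50, geometry):
        fn = surface_reference(case50["plan"].total_dose, geometry)
        sz = geometry.unwrapped()[:20]
        wrapped = sz + np.array([geometry.circumference_mm, 0.0])
        np.testing.assert_allclose(fn(sz), fn(wrapped), rtol=1e-9)

    def test_local_curvature_flags_penumbra_not_plateau(self, case50, geometry):
        fn = surface_reference(case50["plan"].total_dose, geometry)
        curv = local_curvature(fn, geometry.unwrapped(), 3.0)
        planned = case50["planned"].composite
        # the hottest diode sits on an entrance plateau: low curvature
        assert curv[np.argmax(planned)] < 0.01 * planned.max()
        assert curv.max() > 0.01 * planned.max()


class TestRoiGamma:
    def test_identity_and_empty_roi(self, case50):
        plan = case50["plan"]
        res = gamma_roi_3d(plan.total_dose, plan.total_dose,
                           case50["rois"]["target"], GammaCriteria(2, 2))
        assert res.passing_rate == 100.0
        np.testing.assert_allclose(res.gamma, 0.0, atol=1e-12)

    def test_low_dose_roi_below_threshold_errors(self, case50):
        plan = case50["plan"]
        scaled = DoseGrid(plan.total_dose.grid, 1.02 * plan.total_dose.values)
        res = gamma_roi_3d(scaled, plan.total_dose, case50["rois"]["peripheral"],
                           GammaCriteria(3, 3, threshold_pct=99.0))
        with pytest.raises(ValueError, match="evaluable"):
            passing_rate(res)
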