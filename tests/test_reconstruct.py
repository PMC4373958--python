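"""Dose reconstruction: error fields, back-projection, recovery properties."""

import numpy as np
import pytest

from virtualqa import (
    DoseGrid,
    ErrorModel,
    build_error_field,
    dvh_metrics,
    isocenter_dose,
    per_beam_relative_errors,
    perturb_plan,
    predicted_isocenter,
    simulate_measurement,
    smooth_interpolate,
)
from virtualqa.arccheck import DiodeReading
from virtualqa.reconstruct import build_error_field as _bef


def _reading(planned, per_beam):
    return DiodeReading(geometry=planned.geometry, per_beam=per_beam,
                        kind="simulated-measurement")


class TestPerBeamErrors:
    def test_zero_and_uniform_errors(self, case50):
        planned = case50["planned"]
        se0 = per_beam_relative_errors(_reading(planned, planned.per_beam.copy()),
                                       planned, 0, 0.0)
        assert np.allclose(se0.entry_error, 0) and np.allclose(se0.exit_error, 0)
        se3 = per_beam_relative_errors(_reading(planned, 1.03 * planned.per_beam),
                                       planned, 0, 0.0)
        np.testing.assert_allclose(se3.entry_error, 0.03, rtol=1e-9)
        np.testing.assert_allclose(se3.exit_error, 0.03, rtol=1e-9)

    def test_floor_excludes_low_dose_diodes(self, case50):
        planned = case50["planned"]
        p = planned.per_beam[0]
        se = per_beam_relative_errors(_reading(planned, planned.per_beam.copy()),
                                      planned, 0, 0.0, floor_fraction=0.01)
        assert len(se.excluded_index) == int((p <= 0.01 * p.max()).sum())
        assert se.n_retained + len(se.excluded_index) == planned.geometry.n_diodes

    def test_hemisphere_partition_for_gantry_zero(self, case50):
        planned = case50["planned"]
        se = per_beam_relative_errors(_reading(planned, planned.per_beam.copy()),
                                      planned, 0, 0.0)
        pos = planned.geometry.positions
        assert np.all(pos[se.entry_index, 1] >= 0)  # source side is +y at 0°
        assert np.all(pos[se.exit_index, 1] < 0)


class TestSmoothInterpolate:
    def test_constant_field_everywhere(self, geometry):
        sz = geometry.unwrapped()[::3]
        fn = smooth_interpolate(sz, np.full(len(sz), 0.02), geometry)
        q = np.column_stack([
            np.linspace(0, geometry.circumference_mm, 40),
            np.linspace(-100, 100, 40),
        ])
        np.testing.assert_allclose(fn(q), 0.02, atol=1e-9)

    def test_exact_at_diodes_and_linear_in_z(self, geometry):
        sz = geometry.unwrapped()
        vals = 0.001 * sz[:, 1]
        fn = smooth_interpolate(sz, vals, geometry)
        np.testing.assert_allclose(fn(sz), vals, atol=1e-9)
        interior = np.column_stack([
            np.full(20, geometry.circumference_mm / 2),
            np.linspace(-80, 80, 20),
        ])
        np.testing.assert_allclose(fn(interior), 0.001 * interior[:, 1], atol=1e-9)

    def test_no_overshoot(self, geometry):
        rng = np.random.default_rng(1)
        sz = geometry.unwrapped()
        vals = rng.uniform(-0.05, 0.05, len(sz))
        fn = smooth_interpolate(sz, vals, geometry)
        q = np.column_stack([
            rng.uniform(0, geometry.circumference_mm, 500),
            rng.uniform(-130, 130, 500),
        ])
        out = fn(q)
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12

    def test_too_few_points_rejected(self, geometry):
        with pytest.raises(ValueError, match="too few"):
            smooth_interpolate(geometry.unwrapped()[:3], np.zeros(3), geometry)


class TestPerturbPlan:
    def _fields(self, case50, measured):
        plan = case50["plan"]
        return [_bef(measured, case50["planned"], b, plan.beams[b].gantry_angle)
                for b in range(plan.n_beams)]

    def test_identity_bit_for_bit(self, case50, geometry):
        plan = case50["plan"]
        m = simulate_measurement(case50["planned"], plan, ErrorModel())[0]
        pert = perturb_plan(plan, self._fields(case50, m), geometry)
        np.testing.assert_array_equal(pert.dose.values, plan.total_dose.values)

    def test_uniform_error_scales_everything(self, case50, geometry):
        plan = case50["plan"]
        m = _reading(case50["planned"], 1.03 * case50["planned"].per_beam)
        pert = perturb_plan(plan, self._fields(case50, m), geometry)
        np.testing.assert_allclose(
            pert.dose.values, 1.03 * plan.total_dose.values,
            rtol=1e-9, atol=1e-4 * plan.total_dose.max)

    def test_single_beam_error_localized(self, case50, geometry):
        plan = case50["plan"]
        per_beam = case50["planned"].per_beam.copy()
        per_beam[1] *= 1.05
        pert = perturb_plan(plan, self._fields(case50, _reading(case50["planned"], per_beam)),
                            geometry)
        diff = pert.dose.values - plan.total_dose.values
        expected = 0.05 * plan.scaled_beam_values(1)
        np.testing.assert_allclose(diff, expected, rtol=1e-6,
                                   atol=1e-4 * plan.total_dose.max)

    @pytest.mark.parametrize("scale", [-0.04, -0.02, 0.02, 0.04])
    def test_global_scale_recovered_in_target_mean(self, case50, geometry, scale):
        plan = case50["plan"]
        m = simulate_measurement(case50["planned"], plan,
                                 ErrorModel(global_scale=scale))[0]
        pert = perturb_plan(plan, self._fields(case50, m), geometry)
        target = case50["rois"]["target"]
        got = pert.dose.values[target.voxels].mean()
        want = (1 + scale) * plan.total_dose.values[target.voxels].mean()
        assert abs(got / want - 1) < 1e-3

    def test_dvh_metrics_scale_with_uniform_error(self, case50, geometry):
        plan = case50["plan"]
        m = _reading(case50["planned"], 1.02 * case50["planned"].per_beam)
        pert = perturb_plan(plan, self._fields(case50, m), geometry)
        for roi in case50["rois"].values():
            a = dvh_metrics(plan.total_dose, roi, 600.0)
            b = dvh_metrics(pert.dose, roi, 600.0)
            for metric in ("dmean_cgy", "d50_cgy", "d95_cgy"):
                assert getattr(b, metric) == pytest.approx(
                    1.02 * getattr(a, metric), abs=1.0)

    def test_predicted_isocenter_recovery(self, case50, geometry):
        plan = case50["plan"]
        m = simulate_measurement(case50["planned"], plan,
                                 ErrorModel(global_scale=0.04))[0]
        pert = perturb_plan(plan, self._fields(case50, m), geometry)
        assert predicted_isocenter(pert) == pytest.approx(
            1.04 * isocenter_dose(plan.total_dose), rel=1e-3)

    def test_wrong_field_count_rejected(self, case50, geometry):
        with pytest.raises(ValueError, match="one error field per beam"):
            perturb_plan(case50["plan"], [], geometry)
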