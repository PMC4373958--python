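"""Virtual planner: apertures, closed-form beam model, normalization."""

import math

import numpy as np
import pytest

from virtualqa import (
    BeamModel,
    DoseGrid,
    beam_dose,
    bev_aperture,
    compose_plan,
    cylinder_mask,
    isocenter_dose,
    make_grid,
    normalize_to_coverage,
)


@pytest.fixture(scope="module")
def target50_1mm():
    g = make_grid((70, 70, 70), (1, 1, 1))
    return cylinder_mask(g, 50, 50, name="target")


class TestBevAperture:
    def test_bounding_box_with_margin(self, target50_1mm):
        ap = bev_aperture(target50_1mm, 0.0, margin_mm=3.0)
        assert ap.bounding_box_mm() == (56.0, 56.0)

    def test_zero_margin_is_silhouette(self, target50_1mm):
        ap = bev_aperture(target50_1mm, 0.0, margin_mm=0.0)
        w_u, w_v = ap.bounding_box_mm()
        assert w_u == pytest.approx(50.0, abs=1.0)
        assert w_v == pytest.approx(50.0, abs=1.0)

    def test_rotation_invariant_for_cylinder(self, target50_1mm):
        boxes = {bev_aperture(target50_1mm, a).bounding_box_mm() for a in (0, 72, 144)}
        assert len(boxes) == 1

    def test_field_limit_clipping_warns(self):
        g = make_grid((120, 120, 70), (1, 1, 1))
        big = cylinder_mask(g, 100, 50)
        with pytest.warns(UserWarning, match="clip"):
            ap = bev_aperture(big, 0.0, margin_mm=3.0, field_limit_mm=100.0)
        assert ap.bounding_box_mm()[0] <= 100.0

    def test_9cm_target_stays_within_limit(self):
        g = make_grid((110, 110, 70), (1, 1, 1))
        t9 = cylinder_mask(g, 90, 50)
        ap = bev_aperture(t9, 0.0, margin_mm=3.0)
        assert ap.bounding_box_mm()[0] == pytest.approx(96.0, abs=1.0)


@pytest.fixture(scope="module")
def flat_beam():
    """Wide-open beam on a coarse grid: central axis unobstructed."""
    g = make_grid((120, 120, 120), (2, 2, 2))
    t = cylinder_mask(g, 80, 80)
    ap = bev_aperture(t, 0.0, margin_mm=3.0)
    return g, beam_dose(ap, 0.0, g), BeamModel()


class TestBeamDose:
    def test_pdd_peak_on_central_axis(self, flat_beam):
        g, dose, model = flat_beam
        y_entry = g.extent_mm[1] / 2.0
        peak = dose.sample((0.0, y_entry - model.d_max_mm, 0.0))
        assert peak == pytest.approx(1.0, abs=0.02)

    def test_exponential_decay_with_inverse_square(self, flat_beam):
        g, dose, model = flat_beam
        y_entry = g.extent_mm[1] / 2.0
        d1, d2 = 40.0, 80.0
        r = dose.sample((0.0, y_entry - d2, 0.0)) / dose.sample((0.0, y_entry - d1, 0.0))
        expected = math.exp(-model.mu * (d2 - d1)) * (
            (model.sad_mm + d1 - model.d_max_mm) / (model.sad_mm + d2 - model.d_max_mm)
        ) ** 2
        assert r == pytest.approx(expected, rel=0.01)

    def test_gaussian_tail_beyond_5_sigma(self, flat_beam):
        g, dose, model = flat_beam
        y_entry = g.extent_mm[1] / 2.0
        depth = 50.0
        on_axis = dose.sample((0.0, y_entry - depth, 0.0))
        half_width = 43.0  # 80 mm target / 2 + 3 mm margin
        off = dose.sample((half_width + 5 * model.sigma_mm, y_entry - depth, 0.0))
        assert off < 1e-3 * on_axis

    def test_angle_normalized_modulo_360(self, target50_1mm):
        ap = bev_aperture(target50_1mm, 0.0)
        g = make_grid((70, 70, 70), (2, 2, 2))
        d1 = beam_dose(ap, 0.0, g)
        d2 = beam_dose(ap, 360.0, g)
        np.testing.assert_array_equal(d1.values, d2.values)


class TestNormalization:
    def test_uniform_dose_factor(self, phantom_grid2):
        t = cylinder_mask(phantom_grid2, 50, 50, name="target")
        u = DoseGrid(phantom_grid2, np.full(phantom_grid2.shape, 4.0))
        assert normalize_to_coverage(u, t, 600.0) == pytest.approx(150.0)

    def test_gradient_dose_uses_5th_percentile(self, phantom_grid2):
        t = cylinder_mask(phantom_grid2, 50, 50, name="target")
        ax, _, _ = phantom_grid2.axes()
        vals = np.broadcast_to(
            (ax[:, None, None] + 200.0), phantom_grid2.shape).copy()
        d = DoseGrid(phantom_grid2, vals)
        expected = 600.0 / np.percentile(vals[t.voxels], 5)
        assert normalize_to_coverage(d, t, 600.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_dose_raises(self, phantom_grid2):
        t = cylinder_mask(phantom_grid2, 50, 50, name="target")
        z = DoseGrid(phantom_grid2, np.zeros(phantom_grid2.shape))
        with pytest.raises(ValueError):
            normalize_to_coverage(z, t, 600.0)

    def test_idempotent(self, case50):
        plan = case50["plan"]
        target = case50["rois"]["target"]
        again = normalize_to_coverage(plan.total_dose, target, plan.prescription_cgy)
        assert again == pytest.approx(1.0, abs=1e-9)


class TestComposePlan:
    def test_total_is_normalized_sum_of_beams(self, case50):
        plan = case50["plan"]
        acc = plan.per_beam_dose[0].values.copy()
        for b in plan.per_beam_dose[1:]:
            acc += b.values
        np.testing.assert_array_equal(
            plan.total_dose.values, plan.normalization_factor * acc)

    def test_d95_equals_prescription(self, case50):
        plan = case50["plan"]
        target = case50["rois"]["target"]
        d95 = np.percentile(plan.total_dose.values[target.voxels], 5)
        assert d95 == pytest.approx(plan.prescription_cgy, abs=0.5)

    def test_isocenter_runs_hot(self, case50):
        plan = case50["plan"]
        assert isocenter_dose(plan.total_dose) > plan.prescription_cgy

    def test_weights_must_sum_to_one(self, case50):
        with pytest.raises(ValueError, match="sum to 1"):
            compose_plan(case50["rois"]["target"], 600.0,
                         weights=(0.5, 0.5, 0.5, 0.5, 0.5))

    def test_rotational_congruence_of_beams(self, case50):
        """Per-beam doses of the axially symmetric target are congruent
        under 72° rotation about the cylinder axis."""
        plan = case50["plan"]
        rng = np.random.default_rng(0)
        r = rng.uniform(10, 80, 200)
        phi = rng.uniform(0, 2 * np.pi, 200)
        z = rng.uniform(-40, 40, 200)
        pts = np.column_stack([r * np.sin(phi), r * np.cos(phi), z])
        g72 = np.radians(72.0)
        # inverse rotation: beam at 72° is the 0° beam rotated by +72° about z
        rot_inv = np.array([
            [np.cos(g72), -np.sin(g72), 0],
            [np.sin(g72), np.cos(g72), 0],
            [0, 0, 1],
        ])
        d0 = plan.per_beam_dose[0].sample(pts @ rot_inv.T)
        d1 = plan.per_beam_dose[1].sample(pts)
        # tolerance: trilinear curvature error in the penumbra, h²·f″/8 with
        # f″ ~ max/σ² (h = 2 mm spacing, σ = 3 mm) ≈ 5.6% of the beam maximum
        beam_max = plan.per_beam_dose[0].values.max()
        model = BeamModel()
        tol = (2.0**2 / (8 * model.sigma_mm**2) + 0.01) * beam_max
        np.testing.assert_allclose(d0, d1, atol=tol)


class TestIsocenterDose:
    def test_uniform_field(self, phantom_grid2):
        u = DoseGrid(phantom_grid2, np.full(phantom_grid2.shape, 7.5))
        assert isocenter_dose(u) == pytest.approx(7.5)

    def test_linear_field_exact(self):
        g = make_grid((20, 20, 20), (2, 2, 2))
        ax, ay, az = g.axes()
        vals = (
            2.0 * ax[:, None, None] + 3.0 * ay[None, :, None]
            + 0.5 * az[None, None, :] + 100.0
        )
        assert isocenter_dose(DoseGrid(g, vals)) == pytest.approx(100.0, abs=1e-9)
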