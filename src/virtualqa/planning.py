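"""Five-field conformal virtual planner with a closed-form beam model.

The plans mirror the study design: five coplanar beams at gantry
0/72/144/216/288°, apertures conforming to the target's beam's-eye-view
(BEV) silhouette with a 3 mm isotropic margin, a 10 × 10 cm² field limit,
equal beam weights, and normalization so that 95% of the target volume
receives the prescription (D95 = prescription).

The dose engine is a deliberately simple, fully documented closed-form
model (it replaces a commercial pencil-beam engine, whose commissioning
data are not part of this study):

``dose(v) = fluence(u, v) · PDD(depth) · (SAD / (SAD + depth − d_max))²``

* *fluence* — the binary aperture convolved with a 2D Gaussian of σ (the
  penumbra width) in the BEV plane; parallel (non-divergent) projection.
* *PDD* — rises linearly from 0.5 at the surface to 1.0 at the build-up
  depth ``d_max``, then decays as ``exp(−μ (depth − d_max))``.
* *depth* — distance along the beam direction from the point where the ray
  enters the phantom box.

Gantry angle convention: the source of a 0° beam sits on +y, and the angle
increases towards +x, i.e. source direction ``(sin g, cos g, 0)`` and beam
travel direction ``−(sin g, cos g, 0)``. All beams are coplanar (axis z).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_dilation, gaussian_filter

from .grid import DoseGrid, GridSpec
from .phantom import ROIMask

__all__ = [
    "BeamModel",
    "Aperture",
    "BeamSpec",
    "Plan",
    "DEFAULT_BEAM_ANGLES",
    "bev_aperture",
    "beam_dose",
    "compose_plan",
    "normalize_to_coverage",
    "isocenter_dose",
]

DEFAULT_BEAM_ANGLES = (0.0, 72.0, 144.0, 216.0, 288.0)


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the closed-form dose model.

    mu
        Effective linear attenuation beyond the build-up depth (1/mm).
    sigma_mm
        Penumbra width: σ of the 2D Gaussian fluence blur (mm).
    d_max_mm
        Build-up depth at which the PDD peaks (mm).
    sad_mm
        Source–axis distance for the inverse-square factor (mm).
    """

    mu: float = 0.005
    sigma_mm: float = 3.0
    d_max_mm: float = 15.0
    sad_mm: float = 1000.0


@dataclass
class Aperture:
    """Binary aperture on the BEV plane at isocenter.

    Axes: ``u`` (in-plane lateral, perpendicular to the beam) and
    ``v`` (the cylinder axis z). Pixel-centre convention as for GridSpec.
    """

    mask: np.ndarray = field(repr=False)
    spacing_mm: float
    u_axis: np.ndarray = field(repr=False)
    v_axis: np.ndarray = field(repr=False)

    def bounding_box_mm(self) -> tuple[float, float]:
        """(width_u, width_v) of the tight bounding box in mm."""
        if not self.mask.any():
            raise ValueError("empty aperture has no bounding box")
        iu, iv = np.nonzero(self.mask)
        return (
            float((iu.max() - iu.min() + 1) * self.spacing_mm),
            float((iv.max() - iv.min() + 1) * self.spacing_mm),
        )


@dataclass
class BeamSpec:
    gantry_angle: float
    aperture: Aperture
    weight: float
    sad_mm: float = 1000.0

    @property
    def direction(self) -> np.ndarray:
        """Unit vector of beam travel (source → isocenter)."""
        g = math.radians(self.gantry_angle % 360.0)
        return np.array([-math.sin(g), -math.cos(g), 0.0])

    @property
    def source_direction(self) -> np.ndarray:
        """Unit vector from isocenter towards the source."""
        return -self.direction


@dataclass
class Plan:
    """A normalized five-field plan.

    ``per_beam_dose`` holds the weighted but *unnormalized* beam doses, so
    that ``total_dose = normalization_factor × Σ per_beam_dose`` exactly.
    ``scaled_beam_values(b)`` gives beam ``b`` in cGy (normalization
    applied), with ``Σ_b scaled = total`` preserved bit-for-bit.
    """

    target_diameter_mm: float
    prescription_cgy: float
    beams: list[BeamSpec]
    per_beam_dose: list[DoseGrid]
    total_dose: DoseGrid
    normalization_factor: float

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    def scaled_beam_values(self, b: int) -> np.ndarray:
        return self.normalization_factor * self.per_beam_dose[b].values

    def scaled_beam_grid(self, b: int) -> DoseGrid:
        return DoseGrid(self.per_beam_dose[b].grid, self.scaled_beam_values(b))


def bev_aperture(
    target: ROIMask,
    gantry_angle: float,
    margin_mm: float = 3.0,
    field_limit_mm: float = 100.0,
    spacing_mm: float = 1.0,
) -> Aperture:
    """Project the target onto the BEV plane and dilate by the MLC margin.

    Parallel projection along the beam direction; the margin is applied
    isotropically with a disc structuring element. If the dilated aperture
    would exceed the field limit a warning is emitted and the aperture is
    clipped to the limit.
    """
    if target.voxel_count == 0:
        raise ValueError("cannot build an aperture for an empty target")
    g = math.radians(gantry_angle % 360.0)
    pts = target.centers()
    u = pts[:, 0] * math.cos(g) - pts[:, 1] * math.sin(g)
    v = pts[:, 2]

    span_u = (u.max() - u.min()) + 2 * margin_mm
    span_v = (v.max() - v.min()) + 2 * margin_mm
    if span_u > field_limit_mm or span_v > field_limit_mm:
        warnings.warn(
            f"aperture ({span_u:.1f} × {span_v:.1f} mm) exceeds the "
            f"{field_limit_mm:.0f} mm field limit and will be clipped",
            stacklevel=2,
        )

    n = int(round(field_limit_mm / spacing_mm))
    centers = (np.arange(n) + 0.5) * spacing_mm - field_limit_mm / 2.0
    mask = np.zeros((n, n), dtype=bool)
    iu = np.floor((u + field_limit_mm / 2.0) / spacing_mm).astype(int)
    iv = np.floor((v + field_limit_mm / 2.0) / spacing_mm).astype(int)
    keep = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n)
    mask[iu[keep], iv[keep]] = True

    if margin_mm > 0:
        r = int(math.floor(margin_mm / spacing_mm + 1e-9))
        di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
        selem = (di**2 + dj**2) * spacing_mm**2 <= margin_mm**2 + 1e-9
        mask = binary_dilation(mask, structure=selem)
    return Aperture(mask=mask, spacing_mm=spacing_mm, u_axis=centers, v_axis=centers)


def beam_dose(
    aperture: Aperture,
    gantry_angle: float,
    grid: GridSpec,
    model: BeamModel | None = None,
) -> DoseGrid:
    """Closed-form relative dose (max ≈ 1 on the central axis at d_max)."""
    model = model or BeamModel()
    g = math.radians(gantry_angle % 360.0)
    sin_g, cos_g = math.sin(g), math.cos(g)
    d = np.array([-sin_g, -cos_g, 0.0])  # travel direction

    ax, ay, az = grid.axes()
    X = ax[:, None]
    Y = ay[None, :]
    u2 = X * cos_g - Y * sin_g            # BEV lateral coordinate
    tau = -(X * sin_g + Y * cos_g)        # signed distance along d (0 at isocenter plane)

    # Entry parameter of the ray through each voxel into the phantom box
    # (the grid's covered box). The ray is horizontal, so only x/y slabs matter.
    half = [e / 2.0 for e in grid.extent_mm]
    cx = X - tau * d[0]
    cy = Y - tau * d[1]
    tau_in = np.full(np.broadcast_shapes(cx.shape, cy.shape), -np.inf)
    for c, dk, h in ((cx, d[0], half[0]), (cy, d[1], half[1])):
        if abs(dk) < 1e-12:
            continue
        t1 = (-h - c) / dk
        t2 = (h - c) / dk
        tau_in = np.maximum(tau_in, np.minimum(t1, t2))
    depth = tau - tau_in  # >= 0 for voxels inside the box

    dm = model.d_max_mm
    pdd = np.where(
        depth < dm,
        0.5 + 0.5 * np.clip(depth, 0.0, None) / dm,
        np.exp(-model.mu * (depth - dm)),
    )
    invsq = (model.sad_mm / (model.sad_mm + depth - dm)) ** 2
    axial = pdd * invsq  # (nx, ny)

    fl = gaussian_filter(
        aperture.mask.astype(float), model.sigma_mm / aperture.spacing_mm,
        mode="constant",
    )
    fl_interp = RegularGridInterpolator(
        (aperture.u_axis, aperture.v_axis), fl, method="linear",
        bounds_error=False, fill_value=0.0,
    )
    # fluence depends on (u, z): u varies over (x, y), v is exactly z.
    nz = len(az)
    uu = np.broadcast_to(u2[:, :, None], (*u2.shape, nz))
    vv = np.broadcast_to(az[None, None, :], (*u2.shape, nz))
    fluence = fl_interp(np.stack([uu.ravel(), vv.ravel()], axis=1)).reshape(uu.shape)

    return DoseGrid(grid, np.clip(axial[:, :, None] * fluence, 0.0, None))


def normalize_to_coverage(
    dose: DoseGrid,
    target: ROIMask,
    prescription_cgy: float,
    coverage_pct: float = 95.0,
) -> float:
    """Scale factor making D(coverage) of the target equal the prescription.

    D95 is the (100 − coverage) percentile of the voxel doses in the target
    (linear-interpolated percentile), so after scaling exactly
    ``coverage_pct`` % of the target volume receives ≥ the prescription.
    """
    vals = dose.values[target.voxels]
    if vals.size == 0 or vals.max() <= 0:
        raise ValueError("dose is zero inside the target; cannot normalize")
    d_cov = float(np.percentile(vals, 100.0 - coverage_pct))
    if d_cov <= 0:
        raise ValueError("coverage dose is zero; plan does not cover the target")
    return prescription_cgy / d_cov


def compose_plan(
    target: ROIMask,
    prescription_cgy: float,
    beam_angles: tuple[float, ...] = DEFAULT_BEAM_ANGLES,
    weights: tuple[float, ...] | None = None,
    margin_mm: float = 3.0,
    field_limit_mm: float = 100.0,
    model: BeamModel | None = None,
    target_diameter_mm: float | None = None,
) -> Plan:
    """Build, sum and normalize the conformal plan for one target."""
    model = model or BeamModel()
    n = len(beam_angles)
    if weights is None:
        weights = tuple(1.0 / n for _ in beam_angles)
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("beam weights must sum to 1")

    beams: list[BeamSpec] = []
    per_beam: list[DoseGrid] = []
    grid = target.grid
    for angle, w in zip(beam_angles, weights):
        ap = bev_aperture(target, angle, margin_mm=margin_mm, field_limit_mm=field_limit_mm)
        beams.append(BeamSpec(gantry_angle=angle, aperture=ap, weight=w, sad_mm=model.sad_mm))
        bd = beam_dose(ap, angle, grid, model)
        per_beam.append(DoseGrid(grid, w * bd.values))

    total_raw = per_beam[0].values.copy()
    for b in per_beam[1:]:
        total_raw += b.values
    factor = normalize_to_coverage(DoseGrid(grid, total_raw), target, prescription_cgy)
    if target_diameter_mm is None:
        # infer from the silhouette of the 0° aperture minus the margin
        target_diameter_mm = beams[0].aperture.bounding_box_mm()[0] - 2 * margin_mm
    return Plan(
        target_diameter_mm=float(target_diameter_mm),
        prescription_cgy=float(prescription_cgy),
        beams=beams,
        per_beam_dose=per_beam,
        total_dose=DoseGrid(grid, factor * total_raw),
        normalization_factor=factor,
    )


def isocenter_dose(dose: DoseGrid) -> float:
    """Trilinear dose sample at the isocenter (0, 0, 0)."""
    return dose.sample((0.0, 0.0, 0.0))
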