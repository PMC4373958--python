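"""Helical diode-array geometry and simulated measurements.

This module is the synthetic stand-in for the physical detector + linac:
it builds the 1,386-diode helical lattice (66 angular columns × 21 axial
rows on a 21 cm diameter / 21 cm long cylinder, 10 mm pitch, 5.45° between
columns), samples planned per-beam doses at the diode positions, and
produces simulated "measured" readings under a configurable error model:

* a global calibration/output offset (one multiplicative factor);
* a field-size-dependent diode response, piecewise linear through the
  calibration points (−1.1% at a 5 × 5 cm² field, +1.3% at 25 × 25 cm²),
  applied per beam via the beam's equivalent-square field size;
* a rigid setup shift (readings re-sampled at shifted positions);
* zero-mean multiplicative Gaussian reading noise, independent per diode,
  per beam and per replicate.

With every error switched off the simulated reading reproduces the planned
reference bit-for-bit (same sampling path), which anchors the clean-chain
identity of the whole pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import DoseGrid
from .planning import Aperture, Plan

__all__ = [
    "DiodeArrayGeometry",
    "DiodeReading",
    "ErrorModel",
    "DEFAULT_FSR_POINTS",
    "build_geometry",
    "sample_dose_at_diodes",
    "sample_plan_at_diodes",
    "equivalent_square_side",
    "field_size_response",
    "simulate_measurement",
    "readings_to_csv",
]

#: Diode-vs-chamber response calibration: (equivalent square side in cm,
#: fractional response error). −1.1% at 5 cm, +1.3% at 25 cm.
DEFAULT_FSR_POINTS = ((5.0, -0.011), (25.0, 0.013))


@dataclass(frozen=True)
class DiodeArrayGeometry:
    """Positions and lattice indexing of the helical diode array.

    The lattice unwraps to a 2D (arc-length ``s``, axial ``z``) plane:
    column ``c`` sits at angle ``c · 360/66``° and is staggered axially by
    ``pitch · c / n_columns`` so consecutive columns trace a helix.
    """

    n_columns: int
    n_rows: int
    cylinder_diameter_mm: float
    cylinder_length_mm: float
    detector_pitch_mm: float
    positions: np.ndarray = field(repr=False)   # (N, 3) mm
    row_index: np.ndarray = field(repr=False)   # (N,)
    col_index: np.ndarray = field(repr=False)   # (N,)

    @property
    def n_diodes(self) -> int:
        return self.n_columns * self.n_rows

    @property
    def radius_mm(self) -> float:
        return self.cylinder_diameter_mm / 2.0

    @property
    def angular_pitch_deg(self) -> float:
        return 360.0 / self.n_columns

    @property
    def circumference_mm(self) -> float:
        return float(np.pi * self.cylinder_diameter_mm)

    def unwrapped(self) -> np.ndarray:
        """(N, 2) coordinates (arc length s ∈ [0, circumference), z)."""
        theta = np.mod(np.arctan2(self.positions[:, 0], self.positions[:, 1]), 2 * np.pi)
        return np.column_stack([self.radius_mm * theta, self.positions[:, 2]])

    def rewrap(self, sz: np.ndarray) -> np.ndarray:
        """Map unwrapped (s, z) points back onto the 3D cylinder surface."""
        sz = np.atleast_2d(sz)
        theta = sz[:, 0] / self.radius_mm
        return np.column_stack([
            self.radius_mm * np.sin(theta),
            self.radius_mm * np.cos(theta),
            sz[:, 1],
        ])


def build_geometry(
    n_columns: int = 66,
    n_rows: int = 21,
    cylinder_diameter_mm: float = 210.0,
    detector_pitch_mm: float = 10.0,
    cylinder_length_mm: float = 210.0,
) -> DiodeArrayGeometry:
    """Construct the staggered single-helix lattice (defaults: 1,386 diodes)."""
    radius = cylinder_diameter_mm / 2.0
    arc_pitch = np.pi * cylinder_diameter_mm / n_columns
    if abs(arc_pitch - detector_pitch_mm) > 0.5:
        raise ValueError(
            f"arc pitch {arc_pitch:.2f} mm inconsistent with detector pitch "
            f"{detector_pitch_mm} mm for {n_columns} columns"
        )
    span = (n_rows - 1) * detector_pitch_mm + detector_pitch_mm * (n_columns - 1) / n_columns
    if span > cylinder_length_mm:
        raise ValueError("axial span of the helix exceeds the cylinder length")
    z0 = -span / 2.0

    cols = np.repeat(np.arange(n_columns), n_rows)
    rows = np.tile(np.arange(n_rows), n_columns)
    theta = np.radians(cols * (360.0 / n_columns))
    z = z0 + rows * detector_pitch_mm + detector_pitch_mm * cols / n_columns
    positions = np.column_stack([radius * np.sin(theta), radius * np.cos(theta), z])
    return DiodeArrayGeometry(
        n_columns=n_columns,
        n_rows=n_rows,
        cylinder_diameter_mm=cylinder_diameter_mm,
        cylinder_length_mm=cylinder_length_mm,
        detector_pitch_mm=detector_pitch_mm,
        positions=positions,
        row_index=rows,
        col_index=cols,
    )


@dataclass
class DiodeReading:
    """Per-diode doses (cGy), per beam and composite.

    ``composite`` is always the exact sum of the per-beam readings.
    ``kind`` is ``"planned-reference"`` or ``"simulated-measurement"``.
    """

    geometry: DiodeArrayGeometry
    per_beam: np.ndarray = field(repr=False)  # (n_beams, N)
    kind: str = "planned-reference"

    def __post_init__(self) -> None:
        self.per_beam = np.atleast_2d(np.asarray(self.per_beam, dtype=float))
        if self.per_beam.shape[1] != self.geometry.n_diodes:
            raise ValueError("per-beam readings do not match the diode count")
        if np.any(self.per_beam < 0):
            raise ValueError("diode readings must be non-negative")

    @property
    def composite(self) -> np.ndarray:
        return self.per_beam.sum(axis=0)

    @property
    def n_beams(self) -> int:
        return self.per_beam.shape[0]


def sample_dose_at_diodes(
    dose: DoseGrid,
    geometry: DiodeArrayGeometry,
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Trilinear sample of one dose grid at every diode position.

    ``offset_mm`` shifts the sampling positions (used for rigid setup
    shifts). Raises if any (shifted) diode leaves the grid, naming the
    first offending diode index.
    """
    pts = geometry.positions - np.asarray(offset_mm, dtype=float)
    inside = dose.grid.contains_points(pts)
    if not inside.all():
        bad = int(np.argmin(inside))
        raise ValueError(f"diode {bad} at {pts[bad]} lies outside the dose grid")
    return dose.interpolator()(pts)


def sample_plan_at_diodes(plan: Plan, geometry: DiodeArrayGeometry) -> DiodeReading:
    """Planned reference reading: per-beam normalized doses at the diodes."""
    per_beam = np.stack([
        sample_dose_at_diodes(plan.scaled_beam_grid(b), geometry)
        for b in range(plan.n_beams)
    ])
    return DiodeReading(geometry=geometry, per_beam=per_beam, kind="planned-reference")


def equivalent_square_side(aperture: Aperture) -> float:
    """Equivalent-square side (cm) of an aperture: 2ab/(a+b) of its box."""
    a_mm, b_mm = aperture.bounding_box_mm()
    return 2.0 * a_mm * b_mm / (a_mm + b_mm) / 10.0


def field_size_response(
    side_cm: float | np.ndarray,
    calibration_points=DEFAULT_FSR_POINTS,
) -> float | np.ndarray:
    """Multiplicative diode response factor for a given field size.

    Piecewise-linear through the calibration points, linearly extrapolated
    with the end-segment slopes outside their range; returns ``1 + error``.
    """
    pts = sorted(calibration_points)
    if len(pts) < 2 or any(b[0] <= a[0] for a, b in zip(pts, pts[1:])):
        raise ValueError("need >= 2 calibration points with increasing field size")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    side = np.asarray(side_cm, dtype=float)
    if np.any(side <= 0):
        raise ValueError("field size must be positive")
    err = np.interp(side, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    err = np.where(side < xs[0], ys[0] + lo_slope * (side - xs[0]), err)
    err = np.where(side > xs[-1], ys[-1] + hi_slope * (side - xs[-1]), err)
    out = 1.0 + err
    return float(out) if np.isscalar(side_cm) else out


@dataclass(frozen=True)
class ErrorModel:
    """Controllable measurement error model; all effects default to off.

    global_scale
        Fractional calibration/output offset (e.g. +0.04 for +4%).
    fsr_points
        Field-size response calibration points, or ``None`` to disable.
    shift_mm
        Rigid setup translation of the detector relative to the plan; a
        diode physically at ``p`` reads the planned dose at ``p − shift``.
    noise_sd
        SD of the zero-mean multiplicative Gaussian reading noise.
    seed
        Base seed; replicate ``r`` uses ``seed + r``.
    """

    global_scale: float = 0.0
    fsr_points: tuple | None = None
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "ErrorModel":
        return replace(self, seed=int(seed))


def simulate_measurement(
    planned: DiodeReading,
    plan: Plan,
    em: ErrorModel,
    n_replicates: int = 1,
) -> list[DiodeReading]:
    """Simulate measured diode readings for ``n_replicates`` deliveries.

    Per beam ``b`` and replicate ``r``::

        reading = planned_b(p − shift) · (1 + global_scale)
                  · field_size_response(eq. square of beam b) · (1 + ε)

    with ``ε ~ N(0, noise_sd)`` i.i.d. per diode/beam/replicate drawn from
    a generator seeded with ``seed + r``. With all errors off the readings
    equal the planned reference bit-for-bit.
    """
    if planned.kind != "planned-reference":
        raise ValueError("simulate_measurement expects a planned-reference reading")
    geometry = planned.geometry
    shift = np.asarray(em.shift_mm, dtype=float)
    out: list[DiodeReading] = []
    fsr = [
        field_size_response(equivalent_square_side(plan.beams[b].aperture), em.fsr_points)
        if em.fsr_points is not None else 1.0
        for b in range(plan.n_beams)
    ]
    for r in range(n_replicates):
        rng = np.random.default_rng(em.seed + r)
        per_beam = np.empty_like(planned.per_beam)
        for b in range(plan.n_beams):
            base = sample_dose_at_diodes(plan.scaled_beam_grid(b), geometry, offset_mm=shift)
            factor = (1.0 + em.global_scale) * fsr[b]
            vals = base * factor
            if em.noise_sd > 0:
                vals = vals * (1.0 + rng.normal(0.0, em.noise_sd, geometry.n_diodes))
            per_beam[b] = np.clip(vals, 0.0, None)
        out.append(DiodeReading(geometry=geometry, per_beam=per_beam,
                                kind="simulated-measurement"))
    return out


def readings_to_csv(reading: DiodeReading) -> str:
    """CSV export (diode index, lattice row/column, x, y, z, per-beam, composite)."""
    g = reading.geometry
    buf = io.StringIO()
    beams = ",".join(f"beam_{b}" for b in range(reading.n_beams))
    buf.write(f"diode,row,col,x_mm,y_mm,z_mm,{beams},composite\n")
    comp = reading.composite
    for i in range(g.n_diodes):
        beam_vals = ",".join(f"{reading.per_beam[b, i]:.6g}" for b in range(reading.n_beams))
        x, y, z = g.positions[i]
        buf.write(f"{i},{g.row_index[i]},{g.col_index[i]},"
                  f"{x:.4f},{y:.4f},{z:.4f},{beam_vals},{comp[i]:.6g}\n")
    return buf.getvalue()
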