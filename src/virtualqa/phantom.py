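"""Virtual cylindrical phantom and region-of-interest masks.

The study geometry is a homogeneous 26.5 × 26.5 × 27.0 cm box phantom with
three concentric ROIs drawn around the isocenter on the cranio-caudal axis:

* ``target`` — a cylinder of 1/3/5/7/9 cm diameter and 5 cm length;
* ``adjacent`` — a 1 cm thick annulus hugging the target (the high-gradient
  organ-at-risk surrogate);
* ``peripheral`` — a 1 cm thick rim annulus at the detector-cylinder radius
  (low-dose surrogate), identical for every target size.

Masks use a strict voxel-centre inclusion rule (a voxel belongs to an ROI
iff its centre is inside the analytic shape); there is no partial-volume
weighting, so mask volumes converge to the analytic volumes as the grid is
refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = [
    "ROIMask",
    "PHANTOM_EXTENT_MM",
    "cylinder_mask",
    "annulus_mask",
    "roi_set",
    "mask_volume_cc",
]

#: Outer dimensions of the phantom box (mm).
PHANTOM_EXTENT_MM = (265.0, 265.0, 270.0)

#: Default geometry of the peripheral rim ROI (mm).
DEFAULT_PERIPHERAL_SPEC = {
    "outer_diameter_mm": 210.0,
    "thickness_mm": 10.0,
    "length_mm": 50.0,
}


@dataclass
class ROIMask:
    """A named boolean volume on a :class:`~virtualqa.grid.GridSpec`."""

    name: str
    grid: GridSpec
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid shape")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def centers(self) -> np.ndarray:
        """(N, 3) physical centres of the masked voxels."""
        idx = np.argwhere(self.voxels)
        return self.grid.origin + (idx + 0.5) * np.asarray(self.grid.spacing)


def _radial_and_axial(grid: GridSpec, center, axis: int):
    """Radial distance from the cylinder axis and axial offset, per voxel."""
    if axis != 2:
        raise NotImplementedError("cylinder axis must be the cranio-caudal (z) axis")
    ax, ay, az = grid.axes()
    cx, cy, cz = center
    r2 = (ax[:, None] - cx) ** 2 + (ay[None, :] - cy) ** 2  # (nx, ny)
    dz = np.abs(az - cz)  # (nz,)
    return np.sqrt(r2), dz


def cylinder_mask(
    grid: GridSpec,
    diameter_mm: float,
    length_mm: float,
    axis: int = 2,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    name: str = "cylinder",
) -> ROIMask:
    """Solid cylinder mask (voxel-centre inclusion, boundary inclusive)."""
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("cylinder diameter and length must be positive")
    radius, half_len = diameter_mm / 2.0, length_mm / 2.0
    bounds = grid.bounds()
    if (
        center[0] - radius < bounds[0][0] or center[0] + radius > bounds[0][1]
        or center[1] - radius < bounds[1][0] or center[1] + radius > bounds[1][1]
        or center[2] - half_len < bounds[2][0] or center[2] + half_len > bounds[2][1]
    ):
        raise ValueError("cylinder does not fit inside the grid")
    r, dz = _radial_and_axial(grid, center, axis)
    vox = (r <= radius)[:, :, None] & (dz <= half_len)[None, None, :]
    return ROIMask(name=name, grid=grid, voxels=vox)


def annulus_mask(
    grid: GridSpec,
    inner_diameter_mm: float,
    thickness_mm: float,
    length_mm: float,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    name: str = "annulus",
) -> ROIMask:
    """Annular (donut) mask: radial distance in (r_in, r_in + thickness]."""
    if thickness_mm <= 0:
        raise ValueError("annulus thickness must be positive (empty mask otherwise)")
    if inner_diameter_mm < 0 or length_mm <= 0:
        raise ValueError("inner diameter must be >= 0 and length positive")
    r_in = inner_diameter_mm / 2.0
    r_out = r_in + thickness_mm
    outer = cylinder_mask(grid, 2 * r_out, length_mm, center=center, name=name)
    r, dz = _radial_and_axial(grid, center, 2)
    vox = ((r > r_in) & (r <= r_out))[:, :, None] & (dz <= length_mm / 2.0)[None, None, :]
    return ROIMask(name=name, grid=grid, voxels=vox & outer.voxels)


def roi_set(
    grid: GridSpec,
    target_diameter_mm: float,
    peripheral_spec: dict | None = None,
) -> dict[str, ROIMask]:
    """Build the target / adjacent-OAR / peripheral-OAR mask triple.

    The adjacent OAR is a 1 cm thick annulus starting at the target surface;
    the peripheral OAR is a rim annulus fixed by ``peripheral_spec`` and
    therefore identical for every target size. Lengths are all 5 cm.
    """
    if target_diameter_mm < max(grid.spacing[:2]):
        raise ValueError("target diameter below grid spacing is not supported")
    spec = dict(DEFAULT_PERIPHERAL_SPEC)
    if peripheral_spec:
        spec.update(peripheral_spec)
    length = 50.0
    adjacent_outer_r = target_diameter_mm / 2.0 + 10.0
    peripheral_inner_r = spec["outer_diameter_mm"] / 2.0 - spec["thickness_mm"]
    if adjacent_outer_r > peripheral_inner_r:
        raise ValueError(
            "adjacent OAR would overlap the peripheral rim "
            f"(outer radius {adjacent_outer_r} mm > rim inner radius {peripheral_inner_r} mm)"
        )
    target = cylinder_mask(grid, target_diameter_mm, length, name="target")
    adjacent = annulus_mask(grid, target_diameter_mm, 10.0, length, name="adjacent")
    peripheral = annulus_mask(
        grid,
        inner_diameter_mm=spec["outer_diameter_mm"] - 2 * spec["thickness_mm"],
        thickness_mm=spec["thickness_mm"],
        length_mm=spec["length_mm"],
        name="peripheral",
    )
    for m in (target, adjacent, peripheral):
        if m.voxel_count == 0:
            raise ValueError(f"ROI {m.name!r} is empty on this grid")
    return {"target": target, "adjacent": adjacent, "peripheral": peripheral}


def mask_volume_cc(mask: ROIMask) -> float:
    """Volume of the mask in cc (true-voxel count × voxel volume)."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0
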