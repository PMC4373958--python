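"""Voxel lattice and 3D dose containers.

Coordinate convention (used everywhere in the package): right-handed
patient-style axes in millimetres with the machine isocenter at the origin.
``x`` is lateral, ``y`` is anterior–posterior (gantry 0° irradiates from
+y), and ``z`` is the cranio-caudal axis, which is also the axis of the
cylindrical phantom, of every target/OAR cylinder and of the detector
cylinder.

A :class:`GridSpec` describes a regular half-open voxel lattice: voxel
``(i, j, k)`` has its centre at ``origin + (index + 0.5) * spacing``.
:func:`make_grid` centres the covered extent on the isocenter so that the
isocenter always lies inside the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["GridSpec", "DoseGrid", "make_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel lattice with a physical frame.

    Parameters
    ----------
    shape
        Voxel counts per axis (nx, ny, nz).
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        Position (mm) of the lower corner of voxel (0, 0, 0); the voxel
        centre is at ``origin + spacing / 2``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive counts, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (mm) of the covered box per axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D arrays of voxel-centre coordinates per axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def bounds(self) -> tuple[tuple[float, float], ...]:
        """(lo, hi) physical bounds per axis of the covered box."""
        return tuple(
            (self.origin[a], self.origin[a] + self.shape[a] * self.spacing[a])
            for a in range(3)
        )

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 3) lying inside the covered box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.ones(len(pts), dtype=bool)
        for a, (lo, hi) in enumerate(self.bounds()):
            inside &= (pts[:, a] >= lo) & (pts[:, a] <= hi)
        return inside

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax, ay, az = self.axes()
        return np.meshgrid(ax, ay, az, indexing="ij")


def make_grid(
    extent_mm: tuple[float, float, float],
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> GridSpec:
    """Build an isocenter-centred grid covering at least ``extent_mm``.

    The voxel count per axis is ``ceil(extent / spacing)`` so the covered
    box never falls short of the requested extent, and the box is centred
    on the isocenter (origin of the coordinate frame).
    """
    if any(e <= 0 for e in extent_mm):
        raise ValueError(f"extent must be positive, got {extent_mm}")
    if any(s <= 0 for s in spacing_mm):
        raise ValueError(f"spacing must be positive, got {spacing_mm}")
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent_mm, spacing_mm))
    origin = tuple(-n * s / 2.0 for n, s in zip(shape, spacing_mm))
    return GridSpec(shape=shape, spacing=tuple(float(s) for s in spacing_mm), origin=origin)


@dataclass
class DoseGrid:
    """A scalar dose field (cGy, or relative units before normalization)
    on a regular voxel lattice.

    Values are finite and non-negative; dose outside the phantom box is
    zero by construction of the beam model, and sampling outside the grid
    returns zero.
    """

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator over voxel centres; zero outside."""
        return RegularGridInterpolator(
            self.grid.axes(), self.values, method="linear",
            bounds_error=False, fill_value=0.0,
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear sample at points (N, 3) or a single triple."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.interpolator()(pts)
        return out if np.asarray(points).ndim == 2 else float(out[0])

    @property
    def max(self) -> float:
        return float(self.values.max())

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.values * float(factor))
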