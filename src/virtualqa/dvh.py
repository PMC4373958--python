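"""Cumulative DVHs and scalar dose metrics (Dmean, D50, D95, deviations).

The DVH is an exact voxel-counting cumulative histogram (no partial-volume
weighting, consistent with the centre-inclusion mask rule): at each dose
edge ``d`` the curve records the percentage of ROI voxels receiving ≥ d.
``D_x`` follows the "largest dose with coverage ≥ x%" convention with
linear inter-bin interpolation, clipped to the observed dose range so
degenerate (e.g. uniform) distributions invert exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import DoseGrid
from .phantom import ROIMask

__all__ = [
    "DVHCurve",
    "DVHMetrics",
    "cumulative_dvh",
    "dose_at_volume",
    "mean_dose",
    "dvh_metrics",
    "dose_deviation_pct",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: % of ROI volume receiving at least each edge dose."""

    bin_edges: np.ndarray = field(repr=False)       # cGy, uniform width
    volume_fraction: np.ndarray = field(repr=False)  # %, non-increasing
    min_dose: float
    max_dose: float

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def cumulative_dvh(dose: DoseGrid, roi: ROIMask, bin_width_cgy: float = 1.0) -> DVHCurve:
    """Exact voxel-counting cumulative DVH on uniform dose bins."""
    if bin_width_cgy <= 0:
        raise ValueError("bin width must be positive")
    vals = dose.values[roi.voxels]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    top = vals.max() + 2 * bin_width_cgy
    edges = np.arange(0.0, top, bin_width_cgy)
    # % of voxels with dose >= edge; sorted search keeps this O(n log n)
    svals = np.sort(vals)
    counts = vals.size - np.searchsorted(svals, edges, side="left")
    vf = 100.0 * counts / vals.size
    return DVHCurve(
        bin_edges=edges, volume_fraction=vf,
        min_dose=float(vals.min()), max_dose=float(vals.max()),
    )


def dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """Largest dose covering at least ``volume_pct`` % of the ROI volume."""
    if not 0 < volume_pct <= 100:
        raise ValueError("volume_pct must be in (0, 100]")
    vf, edges = dvh.volume_fraction, dvh.bin_edges
    idx = np.nonzero(vf >= volume_pct)[0]
    if idx.size == 0:
        return float(dvh.min_dose)
    i = int(idx[-1])
    if vf[i] == volume_pct or i == len(edges) - 1:
        d = edges[i]
    else:
        # linear interpolation on the falling segment [edges[i], edges[i+1]]
        d = edges[i] + (vf[i] - volume_pct) / (vf[i] - vf[i + 1]) * dvh.bin_width
    return float(np.clip(d, dvh.min_dose, dvh.max_dose))


def mean_dose(dose: DoseGrid, roi: ROIMask) -> float:
    """Arithmetic mean dose (cGy) over the ROI voxels."""
    vals = dose.values[roi.voxels]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    return float(vals.mean())


@dataclass
class DVHMetrics:
    """Scalar DVH metrics of one ROI, in cGy and as % of prescription."""

    roi: str
    prescription_cgy: float
    dmean_cgy: float
    d50_cgy: float
    d95_cgy: float

    @property
    def dmean_pct(self) -> float:
        return 100.0 * self.dmean_cgy / self.prescription_cgy

    @property
    def d50_pct(self) -> float:
        return 100.0 * self.d50_cgy / self.prescription_cgy

    @property
    def d95_pct(self) -> float:
        return 100.0 * self.d95_cgy / self.prescription_cgy


def dvh_metrics(
    dose: DoseGrid,
    roi: ROIMask,
    prescription_cgy: float,
    bin_width_cgy: float = 1.0,
) -> DVHMetrics:
    """Dmean, D50 and D95 of one ROI (D95 ≤ D50 always holds)."""
    curve = cumulative_dvh(dose, roi, bin_width_cgy)
    return DVHMetrics(
        roi=roi.name,
        prescription_cgy=float(prescription_cgy),
        dmean_cgy=mean_dose(dose, roi),
        d50_cgy=dose_at_volume(curve, 50.0),
        d95_cgy=dose_at_volume(curve, 95.0),
    )


def dose_deviation_pct(predicted_or_measured: float, planned: float) -> float:
    """Absolute dose deviation: 100 · |a − planned| / planned (always ≥ 0)."""
    if planned <= 0:
        raise ValueError("planned dose must be positive")
    return 100.0 * abs(predicted_or_measured - planned) / planned
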