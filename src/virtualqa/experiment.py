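"""Full replicated virtual-QA experiment and report tables.

Runs the whole chain for every target size: ROIs → conformal plan →
planned diode reference → simulated measurements (replicated) → 2D diode
gamma → error back-projection → 3D ROI gamma → DVH metrics and dose
deviations → statistics. The output is a set of tidy, machine-readable
tables mirroring the study's report structure:

* ``table2`` — isocenter dose deviations (chamber-measured vs planned and
  reconstruction-predicted vs planned) by target size, with one-way ANOVA;
* ``table3`` — 2D diode-level gamma passing rates by size × criteria;
* ``table4`` — 3D gamma passing rates by size × ROI × criteria;
* ``table5`` — planned vs predicted DVH metrics (% of prescription), with
  independent t-tests;
* ``table6`` — DVH-metric dose deviations by size, with ANOVA;
* ``table7`` — Pearson correlations between DVH-metric deviations and 3D
  passing rates per ROI × criteria.

Everything is deterministic given the config seed: size ``i``, replicate
``r`` uses seed ``seed + 10000·i + 10·r`` for the diode noise and an
offset stream for the chamber noise.

The isocenter "measurement" is a point sample of the true delivered dose
(the planned dose under the delivery errors: global scale and setup shift,
plus reading noise) — the diode field-size response is a detector artifact
and does not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arccheck import (
    DEFAULT_FSR_POINTS,
    DiodeArrayGeometry,
    DiodeReading,
    ErrorModel,
    build_geometry,
    sample_plan_at_diodes,
    simulate_measurement,
)
from .dvh import dose_deviation_pct, dvh_metrics
from .gamma import GammaCriteria, gamma_diode_2d, gamma_roi_3d
from .grid import make_grid
from .phantom import PHANTOM_EXTENT_MM, roi_set
from .planning import Plan, compose_plan, isocenter_dose
from .reconstruct import build_error_field, perturb_plan, predicted_isocenter
from .stats import anova_oneway, pearson_correlation, t_test_independent

__all__ = ["ExperimentConfig", "ReportTables", "run_experiment",
           "measured_isocenter_dose", "run_single_size"]

#: DVH metrics reported per ROI (D95 for the target only).
ROI_METRICS = {
    "target": ("dmean", "d95", "d50"),
    "adjacent": ("dmean", "d50"),
    "peripheral": ("dmean", "d50"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of the replicated experiment."""

    target_diameters_mm: tuple = (10.0, 30.0, 50.0, 70.0, 90.0)
    prescriptions_cgy: tuple = (200.0, 400.0, 600.0, 800.0, 1000.0)
    replicates: int = 3
    error_model: ErrorModel = ErrorModel(fsr_points=DEFAULT_FSR_POINTS, noise_sd=0.01)
    criteria: tuple = (GammaCriteria(3.0, 3.0), GammaCriteria(2.0, 2.0))
    seed: int = 0
    grid_spacing_mm: float = 1.0
    bin_width_cgy: float = 1.0

    def __post_init__(self) -> None:
        if len(self.target_diameters_mm) != len(self.prescriptions_cgy):
            raise ValueError("diameters and prescriptions must align by index")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class ReportTables:
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    table6: pd.DataFrame
    table7: pd.DataFrame
    records: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict[str, pd.DataFrame]:
        return {f"table{i}": getattr(self, f"table{i}") for i in range(2, 8)}


def measured_isocenter_dose(plan: Plan, em: ErrorModel, rng: np.random.Generator) -> float:
    """Ion-chamber analog: point sample of the true delivered isocenter dose."""
    p = np.array([0.0, 0.0, 0.0]) - np.asarray(em.shift_mm, dtype=float)
    dose = sum(plan.scaled_beam_grid(b).sample(tuple(p)) for b in range(plan.n_beams))
    dose *= 1.0 + em.global_scale
    if em.noise_sd > 0:
        dose *= 1.0 + rng.normal(0.0, em.noise_sd)
    return float(dose)


def _crit_key(c: GammaCriteria) -> str:
    return f"{c.dose_tol_pct:g}_{c.dta_mm:g}"


def run_single_size(
    diameter_mm: float,
    prescription_cgy: float,
    config: ExperimentConfig,
    geometry: DiodeArrayGeometry,
    size_index: int,
) -> list[dict]:
    """All per-replicate records for one target size."""
    sp = config.grid_spacing_mm
    grid = make_grid(PHANTOM_EXTENT_MM, (sp, sp, sp))
    rois = roi_set(grid, diameter_mm)
    plan = compose_plan(rois["target"], prescription_cgy,
                        target_diameter_mm=diameter_mm)
    planned_reading = sample_plan_at_diodes(plan, geometry)
    iso_planned = isocenter_dose(plan.total_dose)
    planned_metrics = {
        name: dvh_metrics(plan.total_dose, roi, prescription_cgy, config.bin_width_cgy)
        for name, roi in rois.items()
    }

    rows = []
    for r in range(config.replicates):
        seed = config.seed + 10000 * size_index + 10 * r
        em = config.error_model.with_seed(seed)
        measured = simulate_measurement(planned_reading, plan, em, n_replicates=1)[0]
        chamber_rng = np.random.default_rng(seed + 7919)
        iso_measured = measured_isocenter_dose(plan, em, chamber_rng)

        efs = [
            build_error_field(measured, planned_reading, b, plan.beams[b].gantry_angle)
            for b in range(plan.n_beams)
        ]
        perturbed = perturb_plan(plan, efs, geometry)
        iso_predicted = predicted_isocenter(perturbed)

        row = {
            "size_cm": diameter_mm / 10.0,
            "prescription_cgy": prescription_cgy,
            "replicate": r,
            "iso_planned_cgy": iso_planned,
            "iso_measured_cgy": iso_measured,
            "iso_predicted_cgy": iso_predicted,
            "iso_planned_pct": 100.0 * iso_planned / prescription_cgy,
            "dev_measured_pct": dose_deviation_pct(iso_measured, iso_planned),
            "dev_predicted_pct": dose_deviation_pct(iso_predicted, iso_planned),
        }
        for crit in config.criteria:
            key = _crit_key(crit)
            res2d = gamma_diode_2d(measured, planned_reading, plan.total_dose, crit)
            row[f"rate2d_{key}"] = res2d.passing_rate
            for name, roi in rois.items():
                res3d = gamma_roi_3d(perturbed.dose, plan.total_dose, roi, crit)
                row[f"rate3d_{name}_{key}"] = res3d.passing_rate
        for name, roi in rois.items():
            pm = planned_metrics[name]
            qm = dvh_metrics(perturbed.dose, roi, prescription_cgy, config.bin_width_cgy)
            for metric in ROI_METRICS[name]:
                planned_val = getattr(pm, f"{metric}_cgy")
                pred_val = getattr(qm, f"{metric}_cgy")
                row[f"planned_{name}_{metric}_pct"] = getattr(pm, f"{metric}_pct")
                row[f"predicted_{name}_{metric}_pct"] = getattr(qm, f"{metric}_pct")
                row[f"dev_{name}_{metric}_pct"] = dose_deviation_pct(pred_val, planned_val)
        rows.append(row)
    return rows


def _agg(df: pd.DataFrame, col: str, with_sd: bool):
    g = df.groupby("size_cm")[col]
    out = g.mean().to_frame("mean")
    if with_sd:
        out["sd"] = g.std(ddof=1)
    out["n"] = g.size()
    return out.reset_index()


def _anova_p(df: pd.DataFrame, col: str, replicates: int) -> float:
    if replicates < 2:
        return float("nan")
    groups = [sub[col].to_numpy() for _, sub in df.groupby("size_cm")]
    return anova_oneway(*groups).p_value


def run_experiment(config: ExperimentConfig) -> ReportTables:
    """Run the replicated experiment and assemble tables 2–7 analogs."""
    geometry = build_geometry()
    rows: list[dict] = []
    for i, (d, rx) in enumerate(zip(config.target_diameters_mm, config.prescriptions_cgy)):
        rows.extend(run_single_size(d, rx, config, geometry, size_index=i))
    records = pd.DataFrame(rows)
    with_sd = config.replicates > 1

    # table 2 — isocenter dose deviations by size
    t2 = []
    for comp, col in (("measured_vs_planned", "dev_measured_pct"),
                      ("predicted_vs_planned", "dev_predicted_pct")):
        agg = _agg(records, col, with_sd)
        agg.insert(0, "comparison", comp)
        agg["p_anova"] = _anova_p(records, col, config.replicates)
        t2.append(agg)
    table2 = pd.concat(t2, ignore_index=True)

    # table 3 — 2D diode-level passing rates
    t3 = []
    for crit in config.criteria:
        col = f"rate2d_{_crit_key(crit)}"
        agg = _agg(records, col, with_sd)
        agg.insert(0, "criteria", crit.label)
        agg["p_anova"] = _anova_p(records, col, config.replicates)
        t3.append(agg)
    table3 = pd.concat(t3, ignore_index=True)

    # table 4 — 3D ROI passing rates
    t4 = []
    for crit in config.criteria:
        for roi in ("target", "adjacent", "peripheral"):
            col = f"rate3d_{roi}_{_crit_key(crit)}"
            agg = _agg(records, col, with_sd)
            agg.insert(0, "roi", roi)
            agg.insert(0, "criteria", crit.label)
            agg["p_anova"] = _anova_p(records, col, config.replicates)
            t4.append(agg)
    table4 = pd.concat(t4, ignore_index=True)

    # table 5 — planned vs predicted DVH metrics (% of prescription)
    t5 = []
    for roi, metrics in ROI_METRICS.items():
        for metric in metrics:
            planned_by_size = records.groupby("size_cm")[
                f"planned_{roi}_{metric}_pct"].first()
            predicted = records[f"predicted_{roi}_{metric}_pct"]
            try:
                p = t_test_independent(planned_by_size, predicted).p_value
            except ValueError:
                p = float("nan")
            t5.append({
                "roi": roi, "metric": metric,
                "planned_mean_pct": planned_by_size.mean(),
                "planned_sd_pct": planned_by_size.std(ddof=1),
                "planned_n": len(planned_by_size),
                "predicted_mean_pct": predicted.mean(),
                "predicted_sd_pct": predicted.std(ddof=1),
                "predicted_n": len(predicted),
                "p_ttest": p,
            })
    table5 = pd.DataFrame(t5)

    # table 6 — DVH-metric deviations by size
    t6 = []
    for roi, metrics in ROI_METRICS.items():
        for metric in metrics:
            col = f"dev_{roi}_{metric}_pct"
            agg = _agg(records, col, with_sd)
            agg.insert(0, "metric", metric)
            agg.insert(0, "roi", roi)
            agg["p_anova"] = _anova_p(records, col, config.replicates)
            t6.append(agg)
    table6 = pd.concat(t6, ignore_index=True)

    # table 7 — correlation of DVH deviations with 3D passing rates
    t7 = []
    for crit in config.criteria:
        for roi, metrics in ROI_METRICS.items():
            rates = records[f"rate3d_{roi}_{_crit_key(crit)}"]
            for metric in metrics:
                devs = records[f"dev_{roi}_{metric}_pct"]
                try:
                    res = pearson_correlation(devs, rates)
                    r_val, p_val = res.statistic, res.p_value
                except ValueError:
                    r_val, p_val = float("nan"), float("nan")
                t7.append({
                    "criteria": crit.label, "roi": roi, "metric": metric,
                    "r": r_val, "p": p_val, "n": len(devs),
                })
    table7 = pd.DataFrame(t7)

    return ReportTables(table2=table2, table3=table3, table4=table4,
                        table5=table5, table6=table6, table7=table7,
                        records=records)
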