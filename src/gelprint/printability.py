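"""Printability verdicts: extrudability, cell safety, shape fidelity.

A formulation is printable on a given machine when (i) the pressure needed
to drive it through the train is within the piston's capacity, (ii) the
wall shear stress in the needle stays below the cell-damage threshold
(80 Pa by default, the level below which reported cell damage is
negligible even for long residence times), and (iii) the printed lattice
holds its shape — directly, or with the help of a sacrificial support
bath (bioplotting).

Line-width prediction follows the volumetric slicing convention used by
piston-driven extruders: the slicer imposes a flow rate that keeps the
line width proportional to the nozzle diameter and independent of print
speed, which is exactly what measured width tables show (width highly
correlated with nozzle size, uncorrelated with speed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .collapse import compare_strategies
from .config import ToolkitConfig
from .flow import system_flow
from .geometry import available_pressure
from .rheology import FlowCurve, PowerLawFluid, fit_power_law

__all__ = [
    "DEFAULT_SHEAR_THRESHOLD",
    "PrintabilityReport",
    "WidthCorrelations",
    "assess_cell_safety",
    "residence_time",
    "predict_line_width",
    "line_volumetric_rate",
    "width_correlations",
    "generate_report",
]

#: wall shear stress (Pa) below which cell damage is negligible
DEFAULT_SHEAR_THRESHOLD = 80.0

RECOMMENDATIONS = ("direct_print", "bioplotting_required", "not_extrudable")


def assess_cell_safety(max_wall_shear_stress: float, threshold: float = DEFAULT_SHEAR_THRESHOLD) -> bool:
    """True when the stress does not exceed the threshold (boundary inclusive)."""
    if max_wall_shear_stress < 0:
        raise ValueError("shear stress must be non-negative")
    return max_wall_shear_stress <= threshold


def residence_time(needle_length: float, mean_velocity: float) -> float:
    """Transit time of a fluid element (or cell) through the needle, s."""
    if needle_length <= 0 or mean_velocity <= 0:
        raise ValueError("length and velocity must be positive")
    return needle_length / mean_velocity


def predict_line_width(
    nozzle_diameter: float, flow_multiplier: float = 1.0, layer_height: float | None = None
) -> float:
    """Printed line width, m: flow_multiplier × nozzle diameter.

    Speed-independent by construction (volumetric slicing).  When the
    slicer flow rate is set to 150%, the multiplier is 1.5.
    """
    if nozzle_diameter <= 0 or flow_multiplier <= 0:
        raise ValueError("nozzle diameter and flow multiplier must be positive")
    if layer_height is not None and layer_height <= 0:
        raise ValueError("layer height must be positive")
    return flow_multiplier * nozzle_diameter


def line_volumetric_rate(width: float, layer_height: float, print_speed: float) -> float:
    """Deposited volumetric rate width × height × speed, m³/s."""
    return width * layer_height * print_speed


@dataclass(frozen=True)
class WidthCorrelations:
    """Stratified Pearson correlations of printed width.

    ``r_nozzle_by_speed``: width vs nozzle diameter at each fixed speed,
    computed on per-condition means (3 nozzle levels).
    ``r_speed_by_nozzle_means``: width vs speed at each fixed nozzle on
    per-condition means (3 points — highly variable under the null).
    ``r_speed_by_nozzle``: the same correlation on the individual
    replicates (speeds × replicates points), the statistically stable form.
    """

    r_nozzle_by_speed: dict[float, float]
    r_speed_by_nozzle_means: dict[float, float]
    r_speed_by_nozzle: dict[float, float]

    @property
    def min_r_nozzle(self) -> float:
        return min(self.r_nozzle_by_speed.values())

    @property
    def max_abs_r_speed(self) -> float:
        return max(abs(v) for v in self.r_speed_by_nozzle.values())


def _safe_pearson(x: np.ndarray, y: np.ndarray, allow_nan: bool = False) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        if allow_nan:
            return float("nan")
        raise ValueError("Pearson correlation undefined: zero variance")
    return float(pearsonr(x, y)[0])


def width_correlations(table: pd.DataFrame) -> WidthCorrelations:
    """Stratified width correlations from a measured line-width table.

    ``table`` needs columns nozzle_diameter, print_speed, measured_width
    with at least 3 distinct levels of each varied factor.
    """
    required = {"nozzle_diameter", "print_speed", "measured_width"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table[["nozzle_diameter", "print_speed", "measured_width"]] <= 0).any().any():
        raise ValueError("table entries must be positive")
    nozzles = np.sort(table["nozzle_diameter"].unique())
    speeds = np.sort(table["print_speed"].unique())
    if nozzles.size < 3 or speeds.size < 3:
        raise ValueError("need at least 3 distinct nozzle diameters and print speeds")

    means = (
        table.groupby(["nozzle_diameter", "print_speed"])["measured_width"]
        .mean()
        .reset_index()
    )
    r_nozzle = {}
    for s in speeds:
        sub = means[means["print_speed"] == s]
        r_nozzle[float(s)] = _safe_pearson(
            sub["nozzle_diameter"].to_numpy(), sub["measured_width"].to_numpy()
        )
    # speed correlations are NaN-safe: a perfectly speed-independent width
    # table (e.g. noise-free synthetic data) has zero width variance at a
    # fixed nozzle, and NaN is the honest value for the undefined r
    r_speed_means, r_speed_repl = {}, {}
    for nz in nozzles:
        sub_m = means[means["nozzle_diameter"] == nz]
        r_speed_means[float(nz)] = _safe_pearson(
            sub_m["print_speed"].to_numpy(), sub_m["measured_width"].to_numpy(),
            allow_nan=True,
        )
        sub_r = table[table["nozzle_diameter"] == nz]
        r_speed_repl[float(nz)] = _safe_pearson(
            sub_r["print_speed"].to_numpy(), sub_r["measured_width"].to_numpy(),
            allow_nan=True,
        )
    return WidthCorrelations(r_nozzle, r_speed_means, r_speed_repl)


@dataclass
class PrintabilityReport:
    """Aggregated verdict for one ink / machine / scaffold combination."""

    label: str | None
    required_pressure: float | None = None  # Pa
    available_pressure: float | None = None  # Pa
    extrudable: bool | None = None
    max_wall_shear_stress: float | None = None  # Pa
    shear_threshold: float = DEFAULT_SHEAR_THRESHOLD
    cell_safe: bool | None = None
    residence_time: float | None = None  # s
    collapse_strain_no_support: float | None = None
    collapse_strain_with_support: float | None = None
    recommendation: str | None = None
    missing_stages: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_text(self) -> str:
        def fmt(v, unit="", scale=1.0, nd=3):
            return "n/a" if v is None else f"{v * scale:.{nd}g}{unit}"

        lines = [
            f"Printability report — {self.label or 'unnamed configuration'}",
            f"  required pressure    : {fmt(self.required_pressure, ' kPa', 1e-3)}",
            f"  available pressure   : {fmt(self.available_pressure, ' MPa', 1e-6)}",
            f"  extrudable           : {self.extrudable}",
            f"  max wall shear stress: {fmt(self.max_wall_shear_stress, ' Pa')}"
            f" (threshold {self.shear_threshold:g} Pa)",
            f"  cell safe            : {self.cell_safe}",
            f"  needle residence time: {fmt(self.residence_time, ' s')}",
            f"  collapse strain      : {fmt(self.collapse_strain_no_support)}"
            f" (no support) / {fmt(self.collapse_strain_with_support)} (bioplotting)",
            f"  recommendation       : {self.recommendation}",
        ]
        for n in self.notes:
            lines.append(f"  note: {n}")
        for m in self.missing_stages:
            lines.append(f"  MISSING STAGE: {m}")
        return "\n".join(lines)


def generate_report(
    config: ToolkitConfig,
    material: FlowCurve | PowerLawFluid | None = None,
) -> PrintabilityReport:
    """Run the full pipeline: fit → flow → capacity → safety → collapse.

    ``material`` overrides the config's fluid; a raw :class:`FlowCurve` is
    power-law fitted first.  Stages that cannot run (missing inputs, solver
    failure) are recorded in ``missing_stages`` and the rest of the report
    is still produced.
    """
    report = PrintabilityReport(label=config.label, shear_threshold=config.shear_threshold)

    if material is None:
        material = config.fluid if config.fluid is not None else config.flow_curve
    if isinstance(material, FlowCurve):
        fluid = fit_power_law(material)
    elif isinstance(material, PowerLawFluid):
        fluid = material
    else:
        report.missing_stages.append("rheology: no fluid or flow curve provided")
        return report

    # extrusion flow and hardware capacity
    try:
        profile = system_flow(config.system, fluid, config.inlet_velocity, "power_law")
        report.required_pressure = profile.total_pressure_drop
        report.max_wall_shear_stress = profile.max_wall_shear_stress
        needle = profile.segment_results[-1]
        report.residence_time = residence_time(needle.length, needle.mean_velocity)
    except Exception as exc:  # pragma: no cover - defensive
        report.missing_stages.append(f"flow: {exc}")
    report.available_pressure = available_pressure(config.hardware, config.system)
    if report.required_pressure is not None:
        report.extrudable = report.required_pressure <= report.available_pressure
    if report.max_wall_shear_stress is not None:
        report.cell_safe = assess_cell_safety(
            report.max_wall_shear_stress, config.shear_threshold
        )

    # scaffold collapse, both strategies
    if config.gel_kv is not None and config.support_kv is not None and config.cell is not None:
        try:
            cmp = compare_strategies(
                config.cell,
                config.gel_kv,
                config.support_kv,
                gravity=config.gravity,
                t_end=config.t_end,
                dt=config.dt,
            )
            report.collapse_strain_no_support = cmp.strain_without
            report.collapse_strain_with_support = cmp.strain_with
            if cmp.without_support.beyond_linear_validity:
                report.notes.append(
                    "no-support collapse strain exceeds 20%: beyond linear validity"
                )
            if cmp.with_support.beyond_linear_validity:
                report.notes.append(
                    "with-support collapse strain exceeds 20%: beyond linear validity"
                )
        except Exception as exc:
            report.missing_stages.append(f"collapse: {exc}")
    else:
        report.missing_stages.append(
            "collapse: Kelvin–Voigt gel/support parameters or scaffold cell not provided"
        )

    report.recommendation = _recommend(report, config.collapse_cutoff)
    return report


def _recommend(report: PrintabilityReport, cutoff: float) -> str | None:
    """Pure function of the numeric report fields."""
    if report.extrudable is None:
        return None
    if not report.extrudable:
        return "not_extrudable"
    s_no = report.collapse_strain_no_support
    s_with = report.collapse_strain_with_support
    if s_no is None:
        return "direct_print" if not report.missing_stages else None
    if s_no <= cutoff:
        return "direct_print"
    if s_with is not None and s_with > cutoff:
        report.notes.append(
            "collapse exceeds the acceptability cutoff even with the support bath"
        )
    return "bioplotting_required"
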