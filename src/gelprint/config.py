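"""Structured configuration for the printability toolkit.

Configs are YAML with nested sections (hardware, segments, material,
scaffold, process, thresholds).  Quantities are SI numbers or strings with
an explicit unit tag, e.g. ``length: "60 mm"`` or ``max_torque: "40 N.cm"``;
they are converted to SI on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import (
    AxisymmetricSegment,
    ExtrusionSystem,
    PrinterHardware,
    default_extrusion_system,
)
from .mesh import ScaffoldUnitCell
from .rheology import FlowCurve, KelvinVoigtMaterial, PowerLawFluid
from . import synthetic

__all__ = ["ToolkitConfig", "parse_quantity", "load_config", "default_config"]

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "cm": 1e-2, "um": 1e-6,
    "m/s": 1.0, "mm/s": 1e-3,
    "n.m": 1.0, "n·m": 1.0, "n.cm": 1e-2, "n.mm": 1e-3,
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6,
    "pa.s": 1.0, "pa·s": 1.0,
    "s": 1.0, "kg/m3": 1.0, "kg/m³": 1.0,
    "m/s2": 1.0, "m/s²": 1.0,
}


def parse_quantity(value) -> float:
    """Convert a number or a '<number> <unit>' string to SI."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            return float(parts[0])
        if len(parts) == 2:
            num, unit = parts
            key = unit.lower()
            if key not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit {unit!r}")
            return float(num) * _UNIT_FACTORS[key]
    raise ValueError(f"cannot parse quantity {value!r}")


@dataclass
class ToolkitConfig:
    """All inputs needed for a full printability assessment."""

    hardware: PrinterHardware
    system: ExtrusionSystem
    fluid: PowerLawFluid | None = None
    flow_curve: FlowCurve | None = None
    gel_kv: KelvinVoigtMaterial | None = None
    support_kv: KelvinVoigtMaterial | None = None
    cell: ScaffoldUnitCell | None = None
    inlet_velocity: float = 1.0e-5
    shear_threshold: float = 80.0
    collapse_cutoff: float = 0.05
    gravity: float = 9.81
    t_end: float = 200.0
    dt: float = 0.5
    label: str | None = None

    def echo_json(self, path: str | Path | None = None) -> str:
        """JSON echo of the parsed configuration, for provenance."""
        d = {
            "label": self.label,
            "hardware": vars(self.hardware).copy(),
            "segments": [vars(s).copy() for s in self.system.segments],
            "fluid": None if self.fluid is None else {"K": self.fluid.K, "n": self.fluid.n},
            "gel_kv": None if self.gel_kv is None else {
                "E": self.gel_kv.E, "eta0": self.gel_kv.eta0, "nu": self.gel_kv.nu,
                "rho": self.gel_kv.rho,
            },
            "support_kv": None if self.support_kv is None else {
                "E": self.support_kv.E, "eta0": self.support_kv.eta0,
                "nu": self.support_kv.nu, "rho": self.support_kv.rho,
            },
            "cell": None if self.cell is None else vars(self.cell).copy(),
            "inlet_velocity": self.inlet_velocity,
            "shear_threshold": self.shear_threshold,
            "collapse_cutoff": self.collapse_cutoff,
            "gravity": self.gravity,
            "t_end": self.t_end,
            "dt": self.dt,
        }
        payload = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _segment_from_dict(d: dict) -> AxisymmetricSegment:
    kind = d["kind"]
    length = parse_quantity(d["length"])
    if kind == "cylinder":
        r = parse_quantity(d["radius"])
        return AxisymmetricSegment.cylinder(length, r)
    return AxisymmetricSegment.cone(
        length, parse_quantity(d["radius_in"]), parse_quantity(d["radius_out"])
    )


def _kv_from_dict(d: dict, label: str | None = None) -> KelvinVoigtMaterial:
    return KelvinVoigtMaterial(
        E=parse_quantity(d["E"]),
        eta0=parse_quantity(d.get("eta0", 0.0)),
        nu=float(d.get("nu", 0.49)),
        rho=parse_quantity(d.get("rho", 1000.0)),
        G0=parse_quantity(d["G0"]) if "G0" in d else None,
        label=label,
    )


def load_config(path: str | Path) -> ToolkitConfig:
    """Parse a YAML config file into a :class:`ToolkitConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    hw = raw.get("hardware", {})
    hardware = PrinterHardware(
        max_torque=parse_quantity(hw.get("max_torque", "40 N.cm")),
        pitch=parse_quantity(hw.get("pitch", "0.8 mm")),
        efficiency=float(hw.get("efficiency", 0.5)),
        duty_fraction=float(hw.get("duty_fraction", 0.8)),
    )
    if "segments" in raw:
        system = ExtrusionSystem(tuple(_segment_from_dict(s) for s in raw["segments"]))
    else:
        system = default_extrusion_system()

    fluid = None
    flow_curve = None
    mat = raw.get("material", {})
    if "K" in mat and "n" in mat:
        fluid = PowerLawFluid(K=float(mat["K"]), n=float(mat["n"]))
    if "flow_curve_csv" in mat:
        csv_path = Path(mat["flow_curve_csv"])
        if not csv_path.is_absolute():
            csv_path = Path(path).parent / csv_path
        flow_curve = FlowCurve.from_csv(csv_path)
    gel_kv = _kv_from_dict(mat["kelvin_voigt"], "gel") if "kelvin_voigt" in mat else None
    support_kv = (
        _kv_from_dict(raw["support"]["kelvin_voigt"], "support")
        if "support" in raw and "kelvin_voigt" in raw["support"]
        else None
    )

    cell = None
    if "scaffold" in raw:
        sc = raw["scaffold"]
        cell = ScaffoldUnitCell(
            strand_width=parse_quantity(sc["strand_width"]),
            layer_height=parse_quantity(sc["layer_height"]),
            inter_fiber_distance=parse_quantity(sc["inter_fiber_distance"]),
            n_layers=int(sc.get("n_layers", 6)),
            out_of_plane_thickness=parse_quantity(sc.get("out_of_plane_thickness", "1 mm")),
        )

    proc = raw.get("process", {})
    thr = raw.get("thresholds", {})
    return ToolkitConfig(
        hardware=hardware,
        system=system,
        fluid=fluid,
        flow_curve=flow_curve,
        gel_kv=gel_kv,
        support_kv=support_kv,
        cell=cell,
        inlet_velocity=parse_quantity(proc.get("inlet_velocity", 1.0e-5)),
        gravity=parse_quantity(proc.get("gravity", 9.81)),
        t_end=parse_quantity(proc.get("t_end", 200.0)),
        dt=parse_quantity(proc.get("dt", 0.5)),
        shear_threshold=parse_quantity(thr.get("shear_stress", 80.0)),
        collapse_cutoff=float(thr.get("collapse_strain", 0.05)),
        label=raw.get("label"),
    )


def default_config(gel: str = "C20_pH3.7", needle_radius: float | None = None) -> ToolkitConfig:
    """Ready-to-run config from the reference fixtures.

    ``gel`` selects a characterised formulation by its concentration/pH
    label; ``needle_radius`` (m) overrides the default 0.2 mm needle.
    """
    fx = synthetic.reference_fixtures()
    if gel not in fx.gels:
        raise KeyError(f"unknown gel {gel!r}; choose from {sorted(fx.gels)}")
    system = fx.system
    if needle_radius is not None:
        system = default_extrusion_system(needle_radius=needle_radius)
    return ToolkitConfig(
        hardware=fx.hardware,
        system=system,
        fluid=fx.gels[gel],
        gel_kv=fx.kv_gels[gel],
        support_kv=fx.support,
        cell=fx.cell,
        label=gel,
    )
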