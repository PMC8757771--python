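"""Axisymmetric extrusion-train geometry and piston hardware.

The extrusion train of a piston-driven bioprinter is described as an
ordered chain of axisymmetric segments from the piston face to the needle
tip: syringe barrel (cylinder), conical taper, and needle (cylinder).
Because the drive is volumetric, kinematics follow from mass conservation
alone:

    v_out = v_in * (A_piston / A_outlet)            (continuity)
    gamma_dot_avg = 8 * v_out / D                   (apparent pipe shear rate)

Hardware capacity comes from the lead screw: a stall torque T, screw pitch
p and efficiency eta give an axial force  F = eta * 2*pi*T / p  (the
standard screw conversion), and the pressure available at the piston face
is F (de-rated by a duty fraction) divided by the piston area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "AxisymmetricSegment",
    "ExtrusionSystem",
    "PrinterHardware",
    "outlet_velocity",
    "average_shear_rate",
    "max_piston_force",
    "available_pressure",
    "default_extrusion_system",
]

_RADIUS_TOL = 1e-9


@dataclass(frozen=True)
class AxisymmetricSegment:
    """One segment of the extrusion train: a cylinder or a linear cone."""

    kind: str  # "cylinder" | "cone"
    length: float  # m
    radius_in: float  # m
    radius_out: float  # m

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "cone"):
            raise ValueError("kind must be 'cylinder' or 'cone'")
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if self.radius_in <= 0 or self.radius_out <= 0:
            raise ValueError("segment radii must be positive")
        if self.kind == "cylinder" and not math.isclose(
            self.radius_in, self.radius_out, rel_tol=1e-12
        ):
            raise ValueError("a cylinder must have equal inlet and outlet radii")

    @classmethod
    def cylinder(cls, length: float, radius: float) -> "AxisymmetricSegment":
        return cls("cylinder", length, radius, radius)

    @classmethod
    def cone(cls, length: float, radius_in: float, radius_out: float) -> "AxisymmetricSegment":
        return cls("cone", length, radius_in, radius_out)

    def radius_at(self, s: float) -> float:
        """Local radius at axial coordinate s in [0, length] along the segment."""
        if not 0.0 <= s <= self.length:
            raise ValueError("axial coordinate outside segment")
        frac = s / self.length
        return self.radius_in + frac * (self.radius_out - self.radius_in)


@dataclass(frozen=True)
class ExtrusionSystem:
    """Ordered chain of segments from piston face to needle tip."""

    segments: tuple[AxisymmetricSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if len(segs) < 1:
            raise ValueError("an extrusion system needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if not math.isclose(a.radius_out, b.radius_in, rel_tol=1e-9, abs_tol=_RADIUS_TOL):
                raise ValueError(
                    f"adjacent segments are not radius-continuous: "
                    f"{a.radius_out} != {b.radius_in}"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def piston_radius(self) -> float:
        return self.segments[0].radius_in

    @property
    def outlet_radius(self) -> float:
        return self.segments[-1].radius_out

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def piston_area(self) -> float:
        return math.pi * self.piston_radius**2

    @property
    def outlet_area(self) -> float:
        return math.pi * self.outlet_radius**2

    def needle(self) -> AxisymmetricSegment:
        """The last segment (conventionally the needle)."""
        return self.segments[-1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps([asdict(s) for s in self.segments], indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass(frozen=True)
class PrinterHardware:
    """Lead-screw piston drive: stall torque (N·m), pitch (m), efficiency
    and the duty fraction of the stall force actually usable in service."""

    max_torque: float
    pitch: float
    efficiency: float
    duty_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.max_torque <= 0 or self.pitch <= 0:
            raise ValueError("torque and pitch must be positive")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in (0, 1]")
        if not 0.0 < self.duty_fraction <= 1.0:
            raise ValueError("duty_fraction must lie in (0, 1]")


def outlet_velocity(system: ExtrusionSystem, inlet_velocity: float) -> float:
    """Mean outlet velocity from continuity (volumetric piston drive)."""
    if inlet_velocity <= 0:
        raise ValueError("inlet velocity must be positive")
    return inlet_velocity * system.piston_area / system.outlet_area


def average_shear_rate(needle_diameter: float, mean_velocity: float) -> float:
    """Apparent (Newtonian) pipe-flow shear rate 8 V / D, 1/s."""
    if needle_diameter <= 0 or mean_velocity <= 0:
        raise ValueError("diameter and velocity must be positive")
    return 8.0 * mean_velocity / needle_diameter


def max_piston_force(hw: PrinterHardware, convention: str = "screw") -> float:
    """Maximum axial piston force from the lead screw, N.

    ``convention="screw"`` (default) uses the torque-to-axial-force screw
    conversion F = eta * 2*pi*T / p.  ``convention="literal"`` drops the
    2*pi factor (F = eta * T / p), kept selectable because the simpler form
    appears in some capacity formulas; the screw form is the one that
    matches measured stall forces of M5 lead-screw extruders.
    """
    if convention == "screw":
        return hw.efficiency * 2.0 * math.pi * hw.max_torque / hw.pitch
    if convention == "literal":
        return hw.efficiency * hw.max_torque / hw.pitch
    raise ValueError("convention must be 'screw' or 'literal'")


def available_pressure(
    hw: PrinterHardware, system: ExtrusionSystem, convention: str = "screw"
) -> float:
    """Pressure the piston can sustain in service, Pa.

    The stall force is de-rated by the hardware duty fraction and divided
    by the piston area.
    """
    return hw.duty_fraction * max_piston_force(hw, convention) / system.piston_area


def default_extrusion_system(
    needle_radius: float = 0.2e-3,
    barrel_radius: float = 6.0e-3,
    barrel_length: float = 60.0e-3,
    taper_length: float = 10.0e-3,
    needle_length: float = 16.0e-3,
) -> ExtrusionSystem:
    """5-ml-syringe-class default train: barrel, conical taper, needle.

    Dimensions are representative of a commercial 5-ml syringe (12 mm bore)
    fitted with a blunt dosing needle; the needle radius is the parameter
    users normally sweep (0.13–0.235 mm covers common gauges).
    """
    return ExtrusionSystem(
        (
            AxisymmetricSegment.cylinder(barrel_length, barrel_radius),
            AxisymmetricSegment.cone(taper_length, barrel_radius, needle_radius),
            AxisymmetricSegment.cylinder(needle_length, needle_radius),
        )
    )
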