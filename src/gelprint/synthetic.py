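"""Seeded generators and reference fixtures for the full toolkit.

Everything the pipeline consumes can be produced here with no external
data: flow-sweep curves with a Herschel–Bulkley backbone and multiplicative
lognormal measurement noise, line-width measurement tables following the
volumetric-slicing width model, and the reference parameter sets of the
characterised peptide-gel formulations (six concentration/pH combinations
of the FEFKFEFKK "F9" gel plus the PVA-PVP sacrificial support copolymer).

Noise is lognormal because both viscosities and widths are strictly
positive; the generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PrinterHardware, ExtrusionSystem, default_extrusion_system
from .mesh import ScaffoldUnitCell
from .rheology import (
    FlowCurve,
    HerschelBulkleyParams,
    KelvinVoigtMaterial,
    PowerLawFluid,
)

__all__ = [
    "FlowCurveSpec",
    "LineWidthSpec",
    "ReferenceFixtures",
    "gen_flow_curve",
    "gen_line_width_table",
    "reference_fixtures",
    "RATE_SPAN",
]

#: measurable shear-rate span of the flow sweeps, 1/s
RATE_SPAN = (0.01, 2000.0)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class FlowCurveSpec:
    """Recipe for a synthetic flow sweep.

    The backbone is Herschel–Bulkley stress tau = tau_y + K rate**n on a
    log-spaced rate grid inside the measurable span; tau_y = 0 gives a
    pure power-law curve.
    """

    hb: HerschelBulkleyParams
    rate_min: float = RATE_SPAN[0]
    rate_max: float = RATE_SPAN[1]
    n_points: int = 50
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if not (RATE_SPAN[0] * (1 - 1e-9) <= self.rate_min < self.rate_max
                <= RATE_SPAN[1] * (1 + 1e-9)):
            raise ValueError(f"rate grid must lie within the measurable span {RATE_SPAN}")


def gen_flow_curve(spec: FlowCurveSpec) -> FlowCurve:
    """Synthetic flow sweep; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    rates = np.geomspace(spec.rate_min, spec.rate_max, spec.n_points)
    stress = spec.hb.stress_at(rates) * _lognormal_noise(rng, spec.noise_cv, rates.size)
    return FlowCurve(shear_rate=rates, viscosity=stress / rates)


@dataclass(frozen=True)
class LineWidthSpec:
    """Full-factorial printed-line width measurement campaign.

    Widths follow the volumetric slicing convention: proportional to the
    nozzle diameter, independent of print speed, with multiplicative
    measurement noise.
    """

    nozzle_diameters: tuple[float, ...] = (0.34e-3, 0.40e-3, 0.47e-3)
    print_speeds: tuple[float, ...] = (7.5e-3, 10.0e-3, 20.0e-3)  # m/s
    replicates: int = 15
    width_multiplier: float = 1.1
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(d <= 0 for d in self.nozzle_diameters) or any(
            s <= 0 for s in self.print_speeds
        ):
            raise ValueError("nozzle diameters and print speeds must be positive")


def gen_line_width_table(spec: LineWidthSpec) -> pd.DataFrame:
    """Measured-width table with columns nozzle_diameter, print_speed,
    measured_width (SI units), one row per replicate."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for noz in spec.nozzle_diameters:
        for speed in spec.print_speeds:
            base = spec.width_multiplier * noz
            widths = base * _lognormal_noise(rng, spec.noise_cv, spec.replicates)
            for wdt in widths:
                rows.append((noz, speed, wdt))
    return pd.DataFrame(rows, columns=["nozzle_diameter", "print_speed", "measured_width"])


# ---------------------------------------------------------------------------
# Reference fixtures: characterised gel formulations and printer hardware
# ---------------------------------------------------------------------------

# power-law (K [Pa s^n], n) per concentration/pH combination
_POWER_LAW = {
    "C20_pH3.7": (5.78, 0.12),
    "C20_pH4.8": (13.46, 0.05),
    "C20_pH4.9": (16.83, 0.02),
    "C30_pH3.7": (13.91, 0.04),
    "C30_pH4.8": (21.18, 0.02),
    "C30_pH4.9": (41.98, 0.02),
}

# Kelvin–Voigt lumped parameters (eta0 [Pa s], G0' [Pa], E [Pa])
_KELVIN_VOIGT = {
    "C20_pH3.7": (231.4, 15.0, 30.0),
    "C20_pH4.8": (895.0, 55.5, 111.0),
    "C20_pH4.9": (1124.0, 130.0, 260.0),
    "C30_pH3.7": (981.4, 64.5, 129.0),
    "C30_pH4.8": (1848.4, 125.0, 250.0),
    "C30_pH4.9": (5237.4, 369.0, 738.0),
}
_SUPPORT_KV = (1500.0, 500.0, 1000.0)

#: needle radii commonly swept in the extrudability study, m
NEEDLE_RADII = (0.13e-3, 0.17e-3, 0.20e-3, 0.235e-3)


@dataclass(frozen=True)
class ReferenceFixtures:
    """Bundle of reference inputs: gels, support bath, hardware, geometry."""

    gels: dict[str, PowerLawFluid]
    kv_gels: dict[str, KelvinVoigtMaterial]
    support: KelvinVoigtMaterial
    hardware: PrinterHardware
    system: ExtrusionSystem
    cell: ScaffoldUnitCell
    needle_radii: tuple[float, ...]
    line_width_spec: LineWidthSpec
    print_settings: dict[str, dict]

    def gel_labels(self) -> list[str]:
        return list(self.gels)

    def to_dict(self) -> dict:
        return {
            "gels": {k: {"K": g.K, "n": g.n} for k, g in self.gels.items()},
            "kelvin_voigt": {
                k: {"eta0": m.eta0, "G0": m.G0, "E": m.E}
                for k, m in self.kv_gels.items()
            },
            "support": {
                "eta0": self.support.eta0,
                "G0": self.support.G0,
                "E": self.support.E,
            },
            "hardware": {
                "max_torque": self.hardware.max_torque,
                "pitch": self.hardware.pitch,
                "efficiency": self.hardware.efficiency,
                "duty_fraction": self.hardware.duty_fraction,
            },
            "needle_radii": list(self.needle_radii),
            "print_settings": self.print_settings,
        }


def reference_fixtures() -> ReferenceFixtures:
    """Reference parameter bundle for the characterised formulations.

    Gel labels encode provenance as concentration (mg/ml) and pH, e.g.
    ``"C30_pH4.9"``.  The Kelvin–Voigt records use the as-published E
    values (equal to 2*G0'); Poisson ratio 0.49 and density 1000 kg/m³
    reflect the high water content of the gels.
    """
    gels = {
        label: PowerLawFluid(K=K, n=n, label=label)
        for label, (K, n) in _POWER_LAW.items()
    }
    kv_gels = {
        label: KelvinVoigtMaterial(E=E, eta0=eta0, nu=0.49, rho=1000.0, G0=G0, label=label)
        for label, (eta0, G0, E) in _KELVIN_VOIGT.items()
    }
    eta0, G0, E = _SUPPORT_KV
    support = KelvinVoigtMaterial(
        E=E, eta0=eta0, nu=0.49, rho=1000.0, G0=G0, label="PVA-PVP support"
    )
    hardware = PrinterHardware(
        max_torque=0.40, pitch=0.8e-3, efficiency=0.5, duty_fraction=0.8
    )
    system = default_extrusion_system(needle_radius=0.20e-3)
    cell = ScaffoldUnitCell(
        strand_width=0.77e-3,
        layer_height=0.55e-3,
        inter_fiber_distance=2.57e-3,
        n_layers=6,
    )
    print_settings = {
        "model_1": {"flow_rate": 1.5, "print_speed": 7.5e-3, "nozzle": 0.77e-3,
                    "layer_height": 0.55e-3, "n_layers": 22, "fill_density": 0.30,
                    "perimeters": 1},
        "model_2": {"flow_rate": 1.5, "print_speed": 7.5e-3, "nozzle": 0.47e-3,
                    "layer_height": 0.35e-3, "n_layers": 34, "fill_density": 0.25,
                    "perimeters": 1},
        "model_3": {"flow_rate": 1.5, "print_speed": 7.5e-3, "nozzle": 0.77e-3,
                    "layer_height": 0.55e-3, "n_layers": 22, "fill_density": 0.30,
                    "perimeters": 0},
    }
    return ReferenceFixtures(
        gels=gels,
        kv_gels=kv_gels,
        support=support,
        hardware=hardware,
        system=system,
        cell=cell,
        needle_radii=NEEDLE_RADII,
        line_width_spec=LineWidthSpec(),
        print_settings=print_settings,
    )
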