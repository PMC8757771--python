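"""Rheological models for shear-thinning hydrogel inks.

Self-assembling peptide hydrogels flow as strongly shear-thinning fluids.
Over the shear-rate window relevant to needle extrusion their apparent
viscosity is well described by the Ostwald–de Waele power law

    eta(gamma_dot) = K * gamma_dot**(n - 1)

with consistency index ``K`` (Pa·s^n) and flow behaviour index ``n``
(dimensionless, n < 1 for shear thinning).  At very low shear rates the
same gels — and the sacrificial support baths used for embedded printing —
show a yield stress, captured here by a Herschel–Bulkley fit
``tau = tau_y + K * gamma_dot**n``.

For the transient collapse analysis the gel is lumped into a Kelvin–Voigt
solid: a Hookean spring ``E`` in parallel with a Newtonian dashpot
``eta0``, both read off low-shear oscillatory rheometry (``E`` from the
low-strain storage modulus G0', ``eta0`` from the low-shear viscosity).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FlowCurve",
    "PowerLawFluid",
    "KelvinVoigtMaterial",
    "HerschelBulkleyParams",
    "LowFitQualityWarning",
    "fit_power_law",
    "viscosity_at",
    "kelvin_voigt_from_moduli",
    "fit_herschel_bulkley",
    "estimate_yield_stress",
]

#: fits below this R² are flagged (good flow-sweep fits exceed it comfortably)
R2_WARNING_THRESHOLD = 0.95


class LowFitQualityWarning(UserWarning):
    """Raised (as a warning, not an error) when a log-log fit has R² < 0.95."""


@dataclass(frozen=True)
class FlowCurve:
    """A measured (or synthetic) steady flow sweep.

    Parameters
    ----------
    shear_rate:
        Strictly increasing, strictly positive shear rates, 1/s.
    viscosity:
        Apparent viscosities at those rates, Pa·s.
    temperature:
        Optional metadata, °C.
    """

    shear_rate: np.ndarray
    viscosity: np.ndarray
    temperature: float | None = None

    def __post_init__(self) -> None:
        rate = np.asarray(self.shear_rate, dtype=float)
        visc = np.asarray(self.viscosity, dtype=float)
        if rate.ndim != 1 or visc.ndim != 1 or rate.size != visc.size:
            raise ValueError("shear_rate and viscosity must be equal-length 1-D arrays")
        if rate.size == 0:
            raise ValueError("flow curve is empty")
        if np.any(rate <= 0) or np.any(visc <= 0):
            raise ValueError("shear rates and viscosities must be strictly positive")
        if np.any(np.diff(rate) <= 0):
            raise ValueError("shear_rate must be strictly increasing")
        object.__setattr__(self, "shear_rate", rate)
        object.__setattr__(self, "viscosity", visc)

    @property
    def shear_stress(self) -> np.ndarray:
        """Shear stress tau = eta * gamma_dot, Pa."""
        return self.viscosity * self.shear_rate

    def __len__(self) -> int:
        return int(self.shear_rate.size)

    def window(self, rate_min: float | None = None, rate_max: float | None = None) -> "FlowCurve":
        """Restrict the curve to shear rates in [rate_min, rate_max]."""
        lo = -np.inf if rate_min is None else rate_min
        hi = np.inf if rate_max is None else rate_max
        mask = (self.shear_rate >= lo) & (self.shear_rate <= hi)
        if not mask.any():
            raise ValueError("no points in the requested shear-rate window")
        return FlowCurve(self.shear_rate[mask], self.viscosity[mask], self.temperature)

    @classmethod
    def from_csv(cls, path: str | Path, temperature: float | None = None) -> "FlowCurve":
        """Read a flow curve from CSV with columns ``shear_rate`` and
        ``viscosity`` (or ``shear_stress``, from which viscosity is derived).
        SI units, '.' decimal separator."""
        df = pd.read_csv(path)
        if "shear_rate" not in df.columns:
            raise ValueError("CSV must contain a 'shear_rate' column")
        rate = df["shear_rate"].to_numpy(float)
        if "viscosity" in df.columns:
            visc = df["viscosity"].to_numpy(float)
        elif "shear_stress" in df.columns:
            visc = df["shear_stress"].to_numpy(float) / rate
        else:
            raise ValueError("CSV must contain 'viscosity' or 'shear_stress'")
        order = np.argsort(rate)
        return cls(rate[order], visc[order], temperature)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "shear_rate": self.shear_rate,
                "viscosity": self.viscosity,
                "shear_stress": self.shear_stress,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PowerLawFluid:
    """Ostwald–de Waele fluid eta = K * gamma_dot**(n-1)."""

    K: float
    n: float
    r_squared: float | None = None
    fit_range: tuple[float, float] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("consistency index K must be positive")
        if self.n <= 0:
            raise ValueError("flow behaviour index n must be positive")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def shear_thinning(self) -> bool:
        return self.n < 1.0

    def viscosity_at(self, shear_rate):
        return viscosity_at(self, shear_rate)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PowerLawFluid":
        p = Path(str(text_or_path))
        raw = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(raw)
        if d.get("fit_range") is not None:
            d["fit_range"] = tuple(d["fit_range"])
        return cls(**d)


@dataclass(frozen=True)
class KelvinVoigtMaterial:
    """Lumped Kelvin–Voigt solid: spring E and dashpot eta0 in parallel.

    ``G0`` records the low-strain storage modulus the spring was derived
    from; ``retardation_time`` is the creep time constant eta0/E.
    """

    E: float
    eta0: float
    nu: float = 0.49
    rho: float = 1000.0
    G0: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("spring constant E must be positive")
        if self.eta0 < 0:
            raise ValueError("dashpot viscosity eta0 must be non-negative")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.rho <= 0:
            raise ValueError("density must be positive")

    @property
    def retardation_time(self) -> float:
        return self.eta0 / self.E


@dataclass(frozen=True)
class HerschelBulkleyParams:
    """tau = tau_y + K * gamma_dot**n (yield stress + power-law branch)."""

    tau_y: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if self.tau_y < 0:
            raise ValueError("yield stress must be non-negative")
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")

    def stress_at(self, shear_rate):
        rate = np.asarray(shear_rate, dtype=float)
        return self.tau_y + self.K * rate**self.n


def fit_power_law(
    curve: FlowCurve,
    fit_range: tuple[float, float] | None = None,
    label: str | None = None,
) -> PowerLawFluid:
    """Fit the power law by ordinary least squares in log-log space.

    Shear rate and viscosity are log-transformed and a straight line is
    fitted; the slope is ``n - 1`` and the intercept ``log K``.  A
    :class:`LowFitQualityWarning` is emitted when R² < 0.95.
    """
    if fit_range is not None:
        curve = curve.window(*fit_range)
    if len(curve) < 3:
        raise ValueError("need at least 3 points to fit the power law")
    x = np.log(curve.shear_rate)
    y = np.log(curve.viscosity)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant viscosity: the straight line is exact
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    r2 = min(1.0, r2)
    if r2 < R2_WARNING_THRESHOLD:
        warnings.warn(
            f"power-law fit R² = {r2:.3f} < {R2_WARNING_THRESHOLD}; the curve "
            "may not be power-law over the chosen window",
            LowFitQualityWarning,
            stacklevel=2,
        )
    return PowerLawFluid(
        K=float(np.exp(intercept)),
        n=float(slope + 1.0),
        r_squared=r2,
        fit_range=(float(curve.shear_rate[0]), float(curve.shear_rate[-1])),
        label=label,
    )


def viscosity_at(fluid: PowerLawFluid, shear_rate):
    """Apparent viscosity K * gamma_dot**(n-1) at one or more shear rates."""
    rate = np.asarray(shear_rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("shear rate must be strictly positive")
    out = fluid.K * rate ** (fluid.n - 1.0)
    return float(out) if np.isscalar(shear_rate) else out


def kelvin_voigt_from_moduli(
    G0: float,
    eta0: float = 0.0,
    nu: float = 0.49,
    rho: float = 1000.0,
    convention: str = "table3",
    label: str | None = None,
) -> KelvinVoigtMaterial:
    """Build a Kelvin–Voigt material from low-shear moduli.

    ``convention="poisson"`` applies the isotropic-elasticity relation
    E = 2 (1 + nu) G0'.  ``convention="table3"`` (default) applies E = 2 G0',
    the relation that reproduces the reference lumped-parameter sets this
    package ships (their printed E values all equal twice G0', which is the
    nu -> 0 limit of the former).
    """
    if G0 <= 0:
        raise ValueError("storage modulus G0 must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    if convention == "poisson":
        E = 2.0 * (1.0 + nu) * G0
    elif convention == "table3":
        E = 2.0 * G0
    else:
        raise ValueError("convention must be 'poisson' or 'table3'")
    return KelvinVoigtMaterial(E=E, eta0=eta0, nu=nu, rho=rho, G0=G0, label=label)


def _hb_model(rate, tau_y, K, n):
    return tau_y + K * rate**n


def fit_herschel_bulkley(curve: FlowCurve) -> HerschelBulkleyParams:
    """Nonlinear least-squares Herschel–Bulkley fit of the stress–rate curve.

    Requires a resolved low-shear plateau (at least 5 points below 1 1/s).
    A fitted negative yield stress is clamped to zero with a warning.
    """
    if int((curve.shear_rate < 1.0).sum()) < 5:
        raise ValueError(
            "need at least 5 points below 1 1/s to resolve the yield-stress plateau"
        )
    rate = curve.shear_rate
    stress = curve.shear_stress
    # initial guess: plateau stress from the lowest rates, power-law tail from
    # the remainder
    tau0 = float(stress[:3].mean()) * 0.9
    tail = stress - tau0
    good = tail > 0
    if good.sum() >= 3:
        slope, intercept = np.polyfit(np.log(rate[good]), np.log(tail[good]), 1)
        n0 = float(np.clip(slope, 0.05, 2.0))
        K0 = float(np.exp(intercept))
    else:  # pragma: no cover - extremely flat curves
        n0, K0 = 0.5, float(stress[-1] / rate[-1] ** 0.5)
    try:
        popt, _ = curve_fit(
            _hb_model, rate, stress, p0=(tau0, K0, n0), maxfev=20000
        )
    except RuntimeError as exc:
        raise ValueError(f"Herschel–Bulkley fit did not converge: {exc}") from exc
    tau_y, K, n = (float(v) for v in popt)
    if tau_y < 0:
        warnings.warn(
            f"fitted yield stress {tau_y:.3g} Pa is negative; clamping to 0",
            UserWarning,
            stacklevel=2,
        )
        tau_y = 0.0
    return HerschelBulkleyParams(tau_y=tau_y, K=K, n=n)


def estimate_yield_stress(curve: FlowCurve) -> float:
    """Yield stress (Pa) from a Herschel–Bulkley fit of the flow curve.

    The value is a convenience estimate of the low-shear stress plateau; for
    materials read off a plot it should be treated as approximate.
    """
    return fit_herschel_bulkley(curve).tau_y
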