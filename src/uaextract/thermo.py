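"""Arrhenius, Van't Hoff / Gibbs thermodynamics, and transport numbers.

Temperature chain for a kinetic series: the pseudo-second-order rate
constants give the activation energy through ln k vs 1/T (Arrhenius); the
saturation concentrations give the extraction equilibrium constant
Ke = Cs/(Cmax - Cs), whose Van't Hoff line ln Ke vs 1/T yields the standard
enthalpy and entropy, and Gibbs energy follows from dG = dH - T*dS =
-R*T*ln Ke.

The Kelvin conversion used throughout is T = degC + 273 exactly (not
273.15): it is the convention under which the study's thermodynamic tables
are internally collinear to their printed precision.

Transport bookkeeping: an effective diffusion coefficient De from the
long-time slope of ln(1 - C/Cs) against t under a first-term Fourier-series
solution (slab by default), a film mass-transfer coefficient Kt from the
initial extraction rate, and the mass-transfer Biot number Bi = Kt*L/De.
The De/Kt estimators are declared modeling assumptions — the geometry and
method behind published values of this kind are rarely stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .kinetics import KineticDataset, PSOFit

__all__ = [
    "R_GAS",
    "CELSIUS_OFFSET",
    "celsius_to_kelvin",
    "ArrheniusFit",
    "VantHoffFit",
    "TransportRecord",
    "arrhenius_fit",
    "equilibrium_constant",
    "vant_hoff_fit",
    "gibbs",
    "gibbs_from_ke",
    "biot",
    "estimate_transport",
]

#: universal gas constant, J/(mol K); fixed, never configurable
R_GAS = 8.314
#: Kelvin offset convention (see module docstring)
CELSIUS_OFFSET = 273.0


def celsius_to_kelvin(t_c) -> np.ndarray | float:
    return np.asarray(t_c, float) + CELSIUS_OFFSET


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = ln k0 - Ea/(R T) regression result; energies in J/mol."""

    ea: float
    k0: float
    r2: float
    residuals: np.ndarray


@dataclass(frozen=True)
class VantHoffFit:
    """ln Ke = -dH/(R T) + dS/R regression result; J/mol and J/(mol K)."""

    dh: float
    ds: float
    r2: float
    residuals: np.ndarray

    def gibbs(self, t_k) -> np.ndarray | float:
        return gibbs(self.dh, self.ds, t_k)


@dataclass(frozen=True)
class TransportRecord:
    """De, Kt and Biot number at one temperature, plus the assumptions used."""

    temperature_c: float
    de: float  # m^2/s
    kt: float  # m/s
    bi: float
    length: float  # characteristic length, m
    geometry: str
    method: str


def _inv_t_regression(temperatures_k, values, label: str):
    t = np.asarray(temperatures_k, float).ravel()
    v = np.asarray(values, float).ravel()
    if t.shape != v.shape or len(t) < 2:
        raise ValueError(f"need >= 2 matched temperatures and {label} values")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if np.any(v <= 0):
        raise ValueError(f"{label} values must be positive")
    res = sp_stats.linregress(1.0 / t, np.log(v))
    fitted = res.intercept + res.slope / t
    return res, np.log(v) - fitted


def arrhenius_fit(temperatures_k, rate_constants) -> ArrheniusFit:
    """Least-squares activation energy from rate constants; Ea in J/mol."""
    res, resid = _inv_t_regression(temperatures_k, rate_constants, "rate constant")
    return ArrheniusFit(
        ea=-res.slope * R_GAS,
        k0=math.exp(res.intercept),
        r2=float(res.rvalue**2),
        residuals=resid,
    )


def equilibrium_constant(cs: float, cmax: float) -> float:
    """Extraction equilibrium constant Ke = Cs/(Cmax - Cs).

    ``cmax`` is the concentration after complete (exhaustive) extraction;
    ``cs`` the saturation concentration reached at this temperature.
    """
    if not 0 < cs < cmax:
        raise ValueError("requires 0 < Cs < Cmax (extraction cannot exceed the extractable total)")
    return cs / (cmax - cs)


def vant_hoff_fit(temperatures_k, ke) -> VantHoffFit:
    """Standard enthalpy and entropy from the ln Ke vs 1/T line."""
    res, resid = _inv_t_regression(temperatures_k, ke, "equilibrium constant")
    return VantHoffFit(
        dh=-res.slope * R_GAS,
        ds=res.intercept * R_GAS,
        r2=float(res.rvalue**2),
        residuals=resid,
    )


def gibbs(dh: float, ds: float, t_k) -> np.ndarray | float:
    """Gibbs free energy dG = dH - T*dS, J/mol."""
    t = np.asarray(t_k, float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive kelvin")
    out = dh - t * ds
    return float(out) if np.isscalar(t_k) else out


def gibbs_from_ke(ke, t_k) -> np.ndarray | float:
    """Gibbs free energy from the equilibrium constant, -R*T*ln Ke."""
    ke_arr = np.asarray(ke, float)
    t = np.asarray(t_k, float)
    if np.any(ke_arr <= 0):
        raise ValueError("Ke must be positive")
    if np.any(t <= 0):
        raise ValueError("temperature must be positive kelvin")
    out = -R_GAS * t * np.log(ke_arr)
    return float(out) if np.isscalar(ke) and np.isscalar(t_k) else out


def biot(kt: float, length: float, de: float) -> float:
    """Mass-transfer Biot number Bi = Kt*L/De."""
    if de <= 0:
        raise ValueError("De must be positive")
    if kt < 0 or length < 0:
        raise ValueError("Kt and L must be nonnegative")
    return kt * length / de

# first-term Fourier coefficients: ln(1 - C/Cs) ~ ln(B) - q * De t / L^2
_GEOMETRY = {
    # geometry: (q, B) with L = half-thickness (slab) or radius (sphere)
    "slab": (math.pi**2 / 4.0, 8.0 / math.pi**2),
    "sphere": (math.pi**2, 6.0 / math.pi**2),
}


def estimate_transport(
    dataset: KineticDataset,
    fit: PSOFit,
    length: float,
    geometry: str = "slab",
) -> TransportRecord:
    """Estimate De, Kt and Bi for one fitted time course.

    De comes from the least-squares slope of ln(1 - Ct/Cs) vs t using the
    first term of the Fourier-series solution for the chosen geometry
    (``slab`` default, ``length`` = half-thickness; ``sphere``, ``length``
    = radius).  Kt uses the initial-rate film model dC/dt|0 = k*Cs^2 =
    Kt/L * Cs, i.e. Kt = k*Cs*L.  Times are minutes; De and Kt are
    returned in SI (m^2/s, m/s).
    """
    if geometry not in _GEOMETRY:
        raise ValueError(f"unknown geometry {geometry!r}")
    if length <= 0:
        raise ValueError("characteristic length must be positive")
    q, _ = _GEOMETRY[geometry]
    mask = (dataset.t > 0) & (dataset.ct < fit.cs)
    if mask.sum() < 2:
        raise ValueError("need >= 2 points with 0 < Ct < Cs for the diffusion slope")
    y = np.log(1.0 - dataset.ct[mask] / fit.cs)
    res = sp_stats.linregress(dataset.t[mask], y)
    if res.slope >= 0:
        raise ValueError("non-decaying approach to saturation; cannot estimate De")
    de = -res.slope * length**2 / q / 60.0  # per min -> per s
    kt = fit.k * fit.cs * length / 60.0
    return TransportRecord(
        temperature_c=dataset.temperature_c,
        de=de,
        kt=kt,
        bi=biot(kt, length, de),
        length=length,
        geometry=geometry,
        method="first-term Fourier slope (De); initial-rate film model (Kt)",
    )
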