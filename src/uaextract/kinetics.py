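"""Pseudo-second-order extraction kinetics.

The solid-liquid extraction time course at a fixed temperature follows

    dC/dt = k (Cs - C)^2,   C(0) = 0
    C(t)  = Cs^2 k t / (1 + Cs k t)

where ``Cs`` is the saturation concentration the extract approaches and
``k`` the second-order rate constant (units 1/(concentration * min)).
Fitting is nonlinear least squares on the closed form, initialised from the
exact linearisation t/C = 1/(k Cs^2) + t/Cs, which is itself exposed as
``method="linearized"`` and doubles as an independent closed-form oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

from .assays import FitMetrics, fit_metrics

__all__ = ["KineticDataset", "PSOFit", "predict_ct", "fit_pso", "fit_pso_series"]


@dataclass
class KineticDataset:
    """One extraction time course at a single temperature."""

    response: str
    temperature_c: float
    t: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float).ravel()
        self.ct = np.asarray(self.ct, float).ravel()
        if self.t.shape != self.ct.shape:
            raise ValueError("t and Ct must have the same length")
        if np.any(self.t < 0):
            raise ValueError("negative extraction time")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ct < 0):
            raise ValueError("negative concentration")


@dataclass
class PSOFit:
    """Fitted pseudo-second-order parameters with goodness of fit."""

    k: float
    cs: float
    se_k: float = float("nan")
    se_cs: float = float("nan")
    metrics: FitMetrics = None
    method: str = "nonlinear"
    response: str = ""
    temperature_c: float = float("nan")

    def predict(self, t) -> np.ndarray:
        return predict_ct(self.k, self.cs, t)


def predict_ct(k: float, cs: float, t) -> np.ndarray | float:
    """Closed-form pseudo-second-order concentration at time ``t`` (min)."""
    if k <= 0 or cs <= 0:
        raise ValueError("k and Cs must be positive")
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("negative time")
    out = cs * cs * k * t_arr / (1.0 + cs * k * t_arr)
    return float(out) if np.isscalar(t) else out


def _linearized_fit(t: np.ndarray, ct: np.ndarray) -> tuple[float, float]:
    """Closed-form estimate from the exact linearisation t/C vs t."""
    mask = (t > 0) & (ct > 0)
    if mask.sum() < 2:
        raise ValueError("need at least 2 positive (t, Ct) points to linearize")
    res = sp_stats.linregress(t[mask], t[mask] / ct[mask])
    if res.slope <= 0 or res.intercept <= 0:
        raise ValueError("linearized fit gave non-positive parameters; data not pseudo-second-order")
    cs = 1.0 / res.slope
    k = res.slope**2 / res.intercept
    return k, cs


def fit_pso(data: KineticDataset, method: str = "nonlinear") -> PSOFit:
    """Estimate (k, Cs) for one time course.

    ``nonlinear`` (default) runs Levenberg-Marquardt least squares on the
    closed form, started from the linearised estimate; ``linearized``
    returns the closed-form estimate itself.
    """
    if len(data.t) < 3:
        raise ValueError("need at least 3 observations to fit")
    if np.all(data.ct == 0):
        raise ValueError("all-zero concentrations")
    k0, cs0 = _linearized_fit(data.t, data.ct)

    if method == "linearized":
        k, cs = k0, cs0
        se_k = se_cs = float("nan")
    elif method == "nonlinear":
        try:
            popt, pcov = sp_optimize.curve_fit(
                lambda t, k_, cs_: cs_ * cs_ * k_ * t / (1.0 + cs_ * k_ * t),
                data.t,
                data.ct,
                p0=[k0, cs0],
                maxfev=20000,
            )
        except RuntimeError as exc:
            fallback = PSOFit(k0, cs0, method="linearized",
                              response=data.response, temperature_c=data.temperature_c)
            exc.fallback = fallback
            raise RuntimeError(
                f"nonlinear kinetic fit did not converge ({exc}); "
                "linearized fallback attached as exc.fallback"
            ) from exc
        k, cs = float(popt[0]), float(popt[1])
        se_k, se_cs = [float(s) for s in np.sqrt(np.diag(pcov))]
    else:
        raise ValueError(f"unknown fit method {method!r}")

    if k <= 0 or cs <= 0:
        raise ValueError("fit produced non-positive parameters")
    if cs < 0.8 * data.ct.max():
        warnings.warn(
            f"fitted Cs={cs:.4g} is below 80% of the largest observed "
            f"concentration {data.ct.max():.4g}", RuntimeWarning,
        )
    pred = predict_ct(k, cs, data.t)
    return PSOFit(
        k, cs, se_k, se_cs,
        metrics=fit_metrics(pred, data.ct),
        method=method,
        response=data.response,
        temperature_c=data.temperature_c,
    )


def fit_pso_series(datasets: list[KineticDataset], method: str = "nonlinear") -> list[PSOFit]:
    """Fit each temperature of a series; warn if k or Cs is not increasing.

    Extraction rate constants and saturation concentrations are expected to
    rise with temperature (Arrhenius / Van't Hoff behaviour); a violation
    usually means noisy data rather than an error, hence a warning.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 temperatures")
    fits = [fit_pso(d, method) for d in sorted(datasets, key=lambda d: d.temperature_c)]
    ks = np.array([f.k for f in fits])
    css = np.array([f.cs for f in fits])
    if np.any(np.diff(ks) <= 0):
        warnings.warn("rate constant k is not increasing with temperature", RuntimeWarning)
    if np.any(np.diff(css) <= 0):
        warnings.warn("saturation concentration Cs is not increasing with temperature", RuntimeWarning)
    return fits
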