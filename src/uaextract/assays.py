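"""Goodness-of-fit statistics and spectrophotometric assay conversions.

The assay helpers are pure unit conversions: Folin-Ciocalteu calibration to
total phenolics (mg gallic-acid equivalent per g), DPPH radical quenching
to percent inhibition, and the 450 nm absorbance of a hexane extract to
beta-carotene concentration via the 1% absorption coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitMetrics",
    "fit_metrics",
    "dpph_inhibition",
    "tpc_from_calibration",
    "beta_carotene",
]

#: absorption coefficient of a 1% beta-carotene solution at 450 nm, AU
BETA_CAROTENE_A1PCT = 2592.0
#: concentration of the 1% standard beta-carotene solution, mg/ml
BETA_CAROTENE_C1PCT = 10.0


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    rmse: float
    chi2: float
    rd: float  # percent mean absolute relative deviation
    n: int


def fit_metrics(
    predicted,
    experimental,
    rd_normalization: str = "n",
    rmse_ddof: int = 1,
) -> FitMetrics:
    """R², RMSE, chi-square and percent relative deviation of a fit.

    R² = 1 - SSE/SST with squared residuals; RMSE = sqrt(SSE/(n - ddof))
    with ddof = 1 by default; chi² = sum((Yp - Ye)²/Ye);
    Rd = (100/n) * sum(|Ye - Yp|/Ye).  ``rd_normalization`` may be ``"n"``
    (default — a single pair then reproduces a plain percent deviation) or
    ``"n-1"``.
    """
    yp = np.asarray(predicted, float).ravel()
    ye = np.asarray(experimental, float).ravel()
    if yp.shape != ye.shape or len(yp) < 2:
        raise ValueError("predicted and experimental must be equal-length, n >= 2")
    if np.any(ye == 0):
        raise ValueError("zero experimental value in chi-square / Rd denominator")
    n = len(yp)
    resid = yp - ye
    sse = float(resid @ resid)
    sst = float(np.sum((ye - ye.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else float("-inf"))
    rmse = float(np.sqrt(sse / (n - rmse_ddof)))
    chi2 = float(np.sum(resid**2 / ye))
    denom = n if rd_normalization == "n" else n - 1
    if rd_normalization not in ("n", "n-1"):
        raise ValueError(f"unknown rd_normalization {rd_normalization!r}")
    rd = float(100.0 / denom * np.sum(np.abs(ye - yp) / np.abs(ye)))
    return FitMetrics(r2=r2, rmse=rmse, chi2=chi2, rd=rd, n=n)


def dpph_inhibition(a_sample: float, a_control: float) -> float:
    """Percent DPPH radical inhibition, (1 - As/Ac) * 100."""
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    if a_sample < 0:
        raise ValueError("absorbance must be nonnegative")
    return (1.0 - a_sample / a_control) * 100.0


def tpc_from_calibration(c: float, volume_ml: float, mass_g: float) -> float:
    """Calibration-line concentration to content per g of dry sample, c*V/w.

    Also used for total flavonoids with a quercetin calibration line.
    """
    if mass_g <= 0:
        raise ValueError("sample mass must be positive")
    if volume_ml < 0 or c < 0:
        raise ValueError("concentration and volume must be nonnegative")
    return c * volume_ml / mass_g


def beta_carotene(
    absorbance: float,
    dilution: float,
    a1pct: float = BETA_CAROTENE_A1PCT,
    c1pct: float = BETA_CAROTENE_C1PCT,
) -> float:
    """Beta-carotene concentration from 450 nm absorbance, A*D/(A1% * C1%)."""
    if absorbance < 0 or dilution < 0:
        raise ValueError("absorbance and dilution must be nonnegative")
    return absorbance * dilution / (a1pct * c1pct)
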