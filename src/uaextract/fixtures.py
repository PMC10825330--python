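"""Published reference tables for the persimmon-peel extraction study.

These transcriptions of the study's printed tables drive structural and
consistency tests and supply calibration anchors for the synthetic-data
generator.  They are reference data, not measured inputs: the raw
experimental observations were never deposited.

Responses throughout: YP total phenolic content (mg GAE/g d.w.), YA
antioxidant activity (% DPPH inhibition), YB total beta-carotenoids
(ug/g d.w.), YF total flavonoids (mg QE/g d.w.).  Unicode minus signs in
the source were normalised to ASCII at transcription time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ann import NetworkParams
from .design import FactorSpec

__all__ = [
    "RESPONSES",
    "FACTORS",
    "WEIGHT_TABLE_FLAT",
    "INFLUENCE_TABLE",
    "OPTIMUM_VALIDATION",
    "KINETIC_PARAMS",
    "TRANSPORT_TABLE",
    "THERMO_TABLE",
    "RESPONSE_RANGES",
    "KINETIC_TEMPERATURES_C",
    "load_factors",
    "load_network_params",
    "kinetic_params_frame",
    "validate_fixtures",
]

RESPONSES = ("YP", "YA", "YB", "YF")

#: extraction temperatures of the kinetic study, degC
KINETIC_TEMPERATURES_C = (30.0, 40.0, 50.0, 60.0)

#: factor levels: (name, notation, minimum, average, maximum)
FACTORS = (
    ("Ultrasonic power, W", "XP", 150.0, 250.0, 350.0),
    ("Temperature, degC", "XT", 30.0, 50.0, 70.0),
    ("Solvent-to-solid ratio, ml/g", "XS", 15.0, 25.0, 35.0),
    ("Solvent concentration, %", "XC", 40.0, 60.0, 80.0),
)

#: the 112 printed network weights/biases, in printed (row-major) order
WEIGHT_TABLE_FLAT = (
    8.11, 2.98, 4.35, -0.08, 6.15, -3.08, 4.64, 1.67,
    2.82, -7.44, 13.95, 1.69, -4.77, -0.41, -1.49, 7.15,
    -1.24, -2.70, 1.07, 1.39, 8.09, 6.46, 3.58, 4.45,
    0.53, 1.19, -3.80, 4.81, 3.62, 5.60, 6.54, 1.38,
    -0.75, -0.90, -0.17, 12.64, -7.44, 6.17, 2.07, -2.74,
    -1.14, 5.65, 3.66, -2.92, 1.31, 0.75, 0.55, 1.71,
    2.82, 0.33, 4.65, 2.47, -5.69, 1.22, -3.58, 5.39,
    -3.16, 3.93, 1.57, 2.49, 3.81, 4.21, 4.38, 3.56,
    7.31, -6.14, -8.06, 7.90, 1.53, -3.35, 0.10, -0.35,
    -1.41, 2.71, 3.44, 0.86, -6.30, -3.23, -5.29, -5.53,
    -0.78, -1.84, -6.06, 5.89, -0.69, -0.03, 1.57, -8.06,
    3.49, 0.32, 4.89, -6.89, -2.29, 1.38, -2.76, -3.70,
    -4.73, -5.77, -2.44, 2.96, -5.44, -1.43, -3.11, -1.19,
    4.10, -1.61, 0.79, 3.98, -1.26, -2.46, 1.00, 0.54,
)

#: signed relative influence of each coded factor on each response
INFLUENCE_TABLE = pd.DataFrame(
    {
        "YP": [0.412, -0.319, -0.249, -0.032],
        "YA": [0.619, 0.504, -0.203, 0.327],
        "YB": [0.425, -0.176, 0.253, -0.244],
        "YF": [0.968, -0.581, -0.284, 0.395],
    },
    index=["XP", "XT", "XS", "XC"],
)

#: experimental vs model-predicted responses at the reported optimum
OPTIMUM_VALIDATION = pd.DataFrame(
    {
        "experimental": [16.698, 69.039, 49.947, 1.817],
        "predicted": [17.860, 70.643, 54.281, 1.962],
        "relative_deviation_pct": [6.960, 2.323, 8.678, 7.988],
    },
    index=list(RESPONSES),
)

#: pseudo-second-order parameters per response and temperature:
#: {response: {T_degC: (k, k_sd, Cs, Cs_sd, R2, chi2, RMSE)}}; k absolute
KINETIC_PARAMS = {
    "YP": {
        30.0: (0.556e-2, 0.011e-2, 16.536, 0.101, 0.944, 0.081, 0.285),
        40.0: (0.597e-2, 0.007e-2, 17.976, 0.055, 0.976, 0.010, 0.101),
        50.0: (0.607e-2, 0.004e-2, 20.968, 0.045, 0.955, 0.007, 0.083),
        60.0: (0.702e-2, 0.019e-2, 22.136, 0.154, 0.978, 0.028, 0.166),
    },
    "YA": {
        30.0: (0.233e-2, 0.008e-2, 74.006, 0.691, 0.986, 0.006, 0.076),
        40.0: (0.332e-2, 0.019e-2, 75.740, 0.998, 0.979, 0.003, 0.059),
        50.0: (0.479e-2, 0.013e-2, 76.519, 0.347, 0.963, 0.006, 0.077),
        60.0: (0.564e-2, 0.018e-2, 81.462, 0.432, 0.959, 0.003, 0.053),
    },
    "YB": {
        30.0: (0.439e-2, 0.014e-2, 45.816, 0.344, 0.961, 0.013, 0.113),
        40.0: (0.497e-2, 0.010e-2, 51.325, 0.242, 0.983, 0.025, 0.158),
        50.0: (0.603e-2, 0.029e-2, 54.314, 0.496, 0.972, 0.790, 0.889),
        60.0: (0.678e-2, 0.036e-2, 60.749, 0.483, 0.965, 0.016, 0.128),
    },
    "YF": {
        30.0: (7.007e-2, 0.333e-2, 1.560, 0.022, 0.948, 0.007, 0.083),
        40.0: (9.518e-2, 0.651e-2, 1.790, 0.028, 0.975, 0.004, 0.059),
        50.0: (9.824e-2, 0.525e-2, 2.058, 0.027, 0.959, 0.019, 0.136),
        60.0: (11.215e-2, 0.471e-2, 2.350, 0.021, 0.990, 0.007, 0.085),
    },
}

#: {response: {T_degC: (De m^2/s, Kt m/s)}}
TRANSPORT_TABLE = {
    "YP": {
        30.0: (1.433e-11, 1.330e-6), 40.0: (1.748e-11, 1.467e-6),
        50.0: (2.111e-11, 1.621e-6), 60.0: (2.555e-11, 1.816e-6),
    },
    "YA": {
        30.0: (2.830e-11, 1.935e-6), 40.0: (3.766e-11, 2.341e-6),
        50.0: (4.760e-11, 2.771e-6), 60.0: (5.362e-11, 3.032e-6),
    },
    "YB": {
        30.0: (3.187e-11, 2.087e-6), 40.0: (3.766e-11, 2.338e-6),
        50.0: (4.497e-11, 2.655e-6), 60.0: (5.093e-11, 2.916e-6),
    },
    "YF": {
        30.0: (1.766e-11, 1.472e-6), 40.0: (2.783e-11, 1.915e-6),
        50.0: (3.158e-11, 2.077e-6), 60.0: (3.912e-11, 2.404e-6),
    },
}

#: {response: {"biot": {T: Bi}, "dh": kJ/mol, "ds": J/(mol K), "dg": {T: kJ/mol}}}
THERMO_TABLE = {
    "YP": {
        "biot": {30.0: 14.111, 40.0: 12.752, 50.0: 11.674, 60.0: 10.804},
        "dh": 51.975, "ds": 177.321,
        "dg": {30.0: -1.753, 40.0: -3.526, 50.0: -5.300, 60.0: -7.073},
    },
    "YA": {
        "biot": {30.0: 10.395, 40.0: 9.448, 50.0: 8.850, 60.0: 8.596},
        "dh": 28.083, "ds": 106.943,
        "dg": {30.0: -4.321, 40.0: -5.390, 50.0: -6.460, 60.0: -7.529},
    },
    "YB": {
        "biot": {30.0: 9.956, 40.0: 9.438, 50.0: 8.974, 60.0: 8.702},
        "dh": 66.896, "ds": 227.280,
        "dg": {30.0: -1.970, 40.0: -4.242, 50.0: -6.515, 60.0: -8.788},
    },
    "YF": {
        "biot": {30.0: 12.669, 40.0: 10.459, 50.0: 9.999, 60.0: 9.341},
        "dh": 44.486, "ds": 148.646,
        "dg": {30.0: -0.554, 40.0: -2.040, 50.0: -3.527, 60.0: -5.013},
    },
}

#: observed experimental response ranges across the 30-run design
RESPONSE_RANGES = {
    "YP": (7.723, 24.619),
    "YA": (51.717, 85.584),
    "YB": (24.782, 56.558),
    "YF": (0.291, 1.970),
}

#: reported activation energies, kJ/mol (YP only via the stated reduction)
ACTIVATION_ENERGIES_KJ = {"YA": 25.407, "YB": 12.556, "YF": 12.188}
#: reported percent reduction of Ea(YP) relative to Ea(YA)
EA_YP_REDUCTION_PCT = 76.521


def load_factors() -> list[FactorSpec]:
    """The four process factors as :class:`FactorSpec` objects."""
    return [FactorSpec(n, s, lo, mid, hi) for n, s, lo, mid, hi in FACTORS]


def load_network_params(layout: str = "u-th-w-to") -> NetworkParams:
    """Partition the 112 printed values into a 4-12-4 parameter set.

    The published table gives a flat sequence; the partition order and
    orientation are an assumption (documented default: u as 12x4 row-major,
    then the 12 hidden biases, then w as 4x12 row-major, then the 4 output
    biases).  Use for structural checks only — never as a numeric oracle.
    """
    vals = np.array(WEIGHT_TABLE_FLAT, float)
    if vals.size != 112:
        raise ValueError(f"expected 112 values, found {vals.size}")
    if layout != "u-th-w-to":
        raise ValueError(f"unknown layout {layout!r}")
    return NetworkParams(
        u=vals[:48].reshape(12, 4),
        th=vals[48:60],
        w=vals[60:108].reshape(4, 12),
        to=vals[108:112],
    )


def kinetic_params_frame() -> pd.DataFrame:
    """Kinetic reference parameters as a tidy frame."""
    rows = []
    for resp, per_t in KINETIC_PARAMS.items():
        for t_c, (k, k_sd, cs, cs_sd, r2, chi2, rmse) in per_t.items():
            rows.append(
                dict(response=resp, temperature_c=t_c, k=k, k_sd=k_sd,
                     cs=cs, cs_sd=cs_sd, r2=r2, chi2=chi2, rmse=rmse)
            )
    return pd.DataFrame(rows)


def validate_fixtures() -> dict[str, dict]:
    """Recompute every fixture-derivable consistency check.

    Returns a report ``{check_name: {"passed": bool, "value": ..., ...}}``;
    failures are report entries, not exceptions.
    """
    from .ga import validate_optimum
    from .thermo import arrhenius_fit, biot, celsius_to_kelvin, gibbs

    report: dict[str, dict] = {}
    t_k = celsius_to_kelvin(np.array(KINETIC_TEMPERATURES_C))

    # activation energies from the kinetic parameters
    ea = {}
    for resp in RESPONSES:
        ks = [KINETIC_PARAMS[resp][t][0] for t in KINETIC_TEMPERATURES_C]
        ea[resp] = arrhenius_fit(t_k, ks).ea / 1000.0
    for resp, ref in ACTIVATION_ENERGIES_KJ.items():
        report[f"arrhenius_ea_{resp}"] = {
            "passed": abs(ea[resp] - ref) / ref < 0.005,
            "value": ea[resp], "reference": ref, "units": "kJ/mol",
        }
    reduction = 100.0 * (1.0 - ea["YP"] / ea["YA"])
    report["ea_yp_reduction"] = {
        "passed": abs(reduction - EA_YP_REDUCTION_PCT) < 0.1,
        "value": reduction, "reference": EA_YP_REDUCTION_PCT, "units": "%",
    }

    # Gibbs collinearity of the thermodynamic table
    for resp, d in THERMO_TABLE.items():
        errs = [
            abs(gibbs(d["dh"] * 1000.0, d["ds"], celsius_to_kelvin(t)) - dg * 1000.0)
            for t, dg in d["dg"].items()
        ]
        report[f"gibbs_collinear_{resp}"] = {
            "passed": max(errs) < 2.0, "value": max(errs), "units": "J/mol",
        }

    # constancy of the implied characteristic length L = Bi*De/Kt
    lengths = [
        THERMO_TABLE[resp]["biot"][t] * de / kt
        for resp in RESPONSES
        for t, (de, kt) in TRANSPORT_TABLE[resp].items()
    ]
    lengths = np.array(lengths)
    spread = (lengths.max() - lengths.min()) / lengths.mean()
    report["implied_length_constancy"] = {
        "passed": spread < 0.005,
        "value": float(lengths.mean()), "relative_spread": float(spread), "units": "m",
    }
    # and the Biot identity itself on the mean length
    l_mean = float(lengths.mean())
    bi_err = max(
        abs(biot(kt, l_mean, de) - THERMO_TABLE[resp]["biot"][t])
        / THERMO_TABLE[resp]["biot"][t]
        for resp in RESPONSES
        for t, (de, kt) in TRANSPORT_TABLE[resp].items()
    )
    report["biot_identity"] = {"passed": bi_err < 0.005, "value": bi_err}

    # optimum-validation arithmetic
    dev = validate_optimum(
        OPTIMUM_VALIDATION["experimental"], OPTIMUM_VALIDATION["predicted"]
    )
    ref = OPTIMUM_VALIDATION["relative_deviation_pct"].to_numpy()
    report["optimum_deviation"] = {
        "passed": bool(np.all(np.abs(dev - ref) < 0.01)),
        "value": dev.tolist(), "reference": ref.tolist(), "units": "%",
    }

    report["weight_table_count"] = {
        "passed": len(WEIGHT_TABLE_FLAT) == 112, "value": len(WEIGHT_TABLE_FLAT),
    }
    return report
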