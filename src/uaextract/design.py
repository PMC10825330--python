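"""Central composite circumscribed (CCC) experiment design.

A four-factor CCC drives the surrogate-model training data: 2^k factorial
points at coded ±1, 2k axial (star) points at coded ±alpha, and replicated
center points.  The default axial distance is the rotatable choice
alpha = 2^(k/4), which equals 2 for four factors.

Two conventions relate the tabulated factor ranges to coded space:

``table-levels-are-axial``
    The tabulated minimum/maximum sit at the axial extremes ±alpha, so the
    factorial cube lies strictly inside the stated range.  This is the
    default, because measured responses never exceed the stated factor
    ranges in the study this package models.
``table-levels-are-factorial``
    The tabulated minimum/maximum are the ±1 factorial levels and the axial
    points extrapolate beyond them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXIAL_CONVENTIONS = ("table-levels-are-axial", "table-levels-are-factorial")

RESPONSES = ("YP", "YA", "YB", "YF")
#: CSV column names used for the four responses.
RESPONSE_COLUMNS = tuple(f"Y_{r[1]}" for r in RESPONSES)


@dataclass(frozen=True)
class FactorSpec:
    """One controllable factor with its low / center / high levels.

    ``low`` and ``high`` are the tabulated extremes of the experimental
    range in natural units; ``center`` is the mid level.
    """

    name: str
    notation: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        for v in (self.low, self.center, self.high):
            if not math.isfinite(v):
                raise ValueError(f"non-finite bound for factor {self.name!r}")
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r} requires low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


def rotatable_alpha(k: int) -> float:
    """Axial distance 2^(k/4) that makes the design rotatable."""
    return 2.0 ** (k / 4.0)


def _coded_step(spec: FactorSpec, alpha: float, axial_convention: str) -> float:
    """Natural-unit size of one coded unit."""
    if axial_convention not in AXIAL_CONVENTIONS:
        raise ValueError(f"unknown axial_convention {axial_convention!r}")
    if spec.high == spec.low:
        raise ValueError(f"degenerate range for factor {spec.name!r}")
    if axial_convention == "table-levels-are-axial":
        return spec.half_range / alpha
    return spec.half_range


def code_value(
    spec: FactorSpec,
    natural: float,
    alpha: float = 2.0,
    axial_convention: str = "table-levels-are-axial",
) -> float:
    """Map a natural factor value to coded units (center -> 0)."""
    step = _coded_step(spec, alpha, axial_convention)
    return (natural - spec.center) / step


def decode_value(
    spec: FactorSpec,
    coded: float,
    alpha: float = 2.0,
    axial_convention: str = "table-levels-are-axial",
) -> float:
    """Inverse of :func:`code_value`."""
    step = _coded_step(spec, alpha, axial_convention)
    return spec.center + coded * step


@dataclass
class DesignTable:
    """A CCD run table with coded and natural coordinates.

    ``data`` holds one row per run with columns ``run_id``, ``point_class``
    (``factorial`` | ``axial`` | ``center``), ``coded_<notation>`` and
    ``natural_<notation>`` per factor, and optionally the response columns
    ``Y_P, Y_A, Y_B, Y_F``.
    """

    factors: list[FactorSpec]
    data: pd.DataFrame
    alpha: float = 2.0
    axial_convention: str = "table-levels-are-axial"
    response_columns: tuple[str, ...] = field(default=RESPONSE_COLUMNS)

    @property
    def coded(self) -> np.ndarray:
        cols = [f"coded_{f.notation}" for f in self.factors]
        return self.data[cols].to_numpy(float)

    @property
    def natural(self) -> np.ndarray:
        cols = [f"natural_{f.notation}" for f in self.factors]
        return self.data[cols].to_numpy(float)

    @property
    def has_responses(self) -> bool:
        return all(c in self.data.columns for c in self.response_columns)

    @property
    def responses(self) -> np.ndarray:
        if not self.has_responses:
            raise ValueError("design table has no responses")
        return self.data[list(self.response_columns)].to_numpy(float)

    def with_responses(self, values: np.ndarray) -> "DesignTable":
        values = np.asarray(values, float)
        if values.shape != (len(self.data), len(self.response_columns)):
            raise ValueError(
                f"responses must have shape {(len(self.data), len(self.response_columns))}"
            )
        data = self.data.copy()
        for j, c in enumerate(self.response_columns):
            data[c] = values[:, j]
        return DesignTable(
            self.factors, data, self.alpha, self.axial_convention, self.response_columns
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        factors: list[FactorSpec],
        alpha: float = 2.0,
        axial_convention: str = "table-levels-are-axial",
    ) -> "DesignTable":
        return cls(factors, pd.read_csv(path), alpha, axial_convention)


def generate_ccd(
    factors: list[FactorSpec],
    axial_convention: str = "table-levels-are-axial",
    n_center: int = 6,
    alpha: float | None = None,
) -> DesignTable:
    """Build the central composite circumscribed design.

    Rows are ordered deterministically: the 2^k factorial corners in binary
    order, then the 2k axial points in factor order (minus before plus),
    then the center replicates.  Run count is ``2**k + 2*k + n_center``.
    """
    k = len(factors)
    if not 2 <= k <= 6:
        raise ValueError("number of factors must be between 2 and 6")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if axial_convention not in AXIAL_CONVENTIONS:
        raise ValueError(f"unknown axial_convention {axial_convention!r}")
    if alpha is None:
        alpha = rotatable_alpha(k)

    rows: list[tuple[str, list[float]]] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(("factorial", list(corner)))
    for i in range(k):
        for s in (-alpha, alpha):
            v = [0.0] * k
            v[i] = s
            rows.append(("axial", v))
    for _ in range(n_center):
        rows.append(("center", [0.0] * k))

    records = []
    for run_id, (cls_, coded) in enumerate(rows, start=1):
        rec: dict[str, object] = {"run_id": run_id, "point_class": cls_}
        for f, c in zip(factors, coded):
            rec[f"coded_{f.notation}"] = c
            rec[f"natural_{f.notation}"] = decode_value(f, c, alpha, axial_convention)
        records.append(rec)
    return DesignTable(list(factors), pd.DataFrame.from_records(records), alpha, axial_convention)
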