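"""Central composite designs (CCD) in coded and natural factor units.

A CCD for ``k`` factors consists of the full two-level factorial (all
``2**k`` sign patterns at coded ±1), two axial (star) points per factor at
coded ±alpha, and replicated center points at the design origin.  Factor
values are expressed either in *natural* units (°C, hours, ...) or in
*coded* units — multiples of the factor's step about its center.

The module also carries the five-factor design used for the
lipase-catalysed esterification study this package models: enzyme loading,
reaction time, temperature, substrate molar ratio (oleic acid to
triethanolamine, expressed as the scalar r of an r:1 ratio) and agitation
speed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ALPHA",
    "DesignPoint",
    "FactorSpec",
    "PointRole",
    "ReactionCondition",
    "code",
    "decode",
    "design_to_frame",
    "esterification_factors",
    "generate_ccd",
    "read_factors",
    "write_design",
    "write_factors",
]

#: Coded distance of the axial (star) points used throughout the study.
DEFAULT_ALPHA = 1.75


@dataclass(frozen=True)
class ReactionCondition:
    """One esterification run setting in natural units."""

    enzyme: float  #: enzyme loading, w/w % of oleic acid
    time: float  #: reaction time, h
    temperature: float  #: reaction temperature, °C
    molar_ratio: float  #: OA:TEA molar ratio as a scalar r (meaning r:1)
    agitation: float  #: agitation speed, r.p.m.

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.enzyme, self.time, self.temperature, self.molar_ratio, self.agitation],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ReactionCondition":
        e, t, temp, r, a = (float(v) for v in values)
        return cls(e, t, temp, r, a)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental variable and its coding transform.

    ``code`` maps natural units to coded units via
    ``(x - center) / step``; ``decode`` is the inverse.  ``step`` is the
    natural-unit width of one coded unit, so coded ±1 are the factorial
    levels and ±alpha the axial levels.
    """

    name: str
    units: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.center) and math.isfinite(self.step)):
            raise ValueError(f"factor {self.name!r}: center/step must be finite")
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")


def code(spec: FactorSpec, natural_value: float) -> float:
    """Convert a natural-unit value to coded units."""
    x = float(natural_value)
    if not math.isfinite(x):
        raise ValueError(f"factor {spec.name!r}: cannot code non-finite value {natural_value!r}")
    return (x - spec.center) / spec.step


def decode(spec: FactorSpec, coded_value: float) -> float:
    """Convert a coded value back to natural units (inverse of :func:`code`)."""
    c = float(coded_value)
    if not math.isfinite(c):
        raise ValueError(f"factor {spec.name!r}: cannot decode non-finite value {coded_value!r}")
    return spec.center + c * spec.step


def esterification_factors() -> list[FactorSpec]:
    """The five design factors of the esterquat synthesis study.

    Centers and steps reproduce the study's coded levels exactly, e.g.
    temperature spans 51.25–68.75 °C across coded ±1.75.
    """
    return [
        FactorSpec("enzyme", "w/w%", center=5.0, step=2.0),
        FactorSpec("time", "h", center=16.0, step=8.0),
        FactorSpec("temperature", "degC", center=60.0, step=5.0),
        FactorSpec("molar_ratio", "mol/mol (r of r:1)", center=2.0, step=1.0),
        FactorSpec("agitation", "rpm", center=400.0, step=150.0),
    ]


class PointRole(str, Enum):
    FACTORIAL = "factorial"
    AXIAL = "axial"
    CENTER = "center"


@dataclass(frozen=True)
class DesignPoint:
    """One design run: coded coordinates, natural coordinates, and role."""

    coded: tuple[float, ...]
    natural: tuple[float, ...]
    role: PointRole

    def condition(self) -> ReactionCondition:
        """Interpret a five-factor point as a reaction condition.

        Valid only for designs built on :func:`esterification_factors`
        (factors in that order).
        """
        if len(self.natural) != 5:
            raise ValueError("condition() requires a five-factor design point")
        return ReactionCondition.from_array(self.natural)


def _make_point(factors: Sequence[FactorSpec], coded: Sequence[float], role: PointRole) -> DesignPoint:
    natural = tuple(decode(f, c) for f, c in zip(factors, coded))
    return DesignPoint(coded=tuple(float(c) for c in coded), natural=natural, role=role)


def generate_ccd(
    factors: Sequence[FactorSpec],
    alpha: float = DEFAULT_ALPHA,
    n_center: int = 8,
) -> list[DesignPoint]:
    """Build a central composite design.

    Returns ``2**k`` factorial points (full two-level enumeration in
    binary-counter order, first factor most significant, −1 before +1),
    then ``2k`` axial points (by factor index, −alpha before +alpha), then
    ``n_center`` center points.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("generate_ccd requires at least one factor")
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if n_center < 0:
        raise ValueError(f"n_center must be >= 0, got {n_center}")

    k = len(factors)
    points: list[DesignPoint] = []
    for signs in itertools.product((-1.0, 1.0), repeat=k):
        points.append(_make_point(factors, signs, PointRole.FACTORIAL))
    for i in range(k):
        for a in (-alpha, alpha):
            coded = [0.0] * k
            coded[i] = float(a)
            points.append(_make_point(factors, coded, PointRole.AXIAL))
    center = [0.0] * k
    for _ in range(n_center):
        points.append(_make_point(factors, center, PointRole.CENTER))
    return points


# ---------------------------------------------------------------------------
# CSV plumbing

_FACTOR_COLUMNS = ["name", "units", "center", "step"]


def read_factors(path) -> list[FactorSpec]:
    """Read a factor table (columns name, units, center, step)."""
    df = pd.read_csv(path)
    missing = [c for c in _FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"factor table {path}: missing columns {missing}")
    return [
        FactorSpec(str(r["name"]), str(r["units"]), float(r["center"]), float(r["step"]))
        for _, r in df.iterrows()
    ]


def write_factors(factors: Iterable[FactorSpec], path) -> None:
    pd.DataFrame(
        [{"name": f.name, "units": f.units, "center": f.center, "step": f.step} for f in factors]
    ).to_csv(path, index=False)


def design_to_frame(factors: Sequence[FactorSpec], points: Sequence[DesignPoint]) -> pd.DataFrame:
    rows = []
    for run, p in enumerate(points, start=1):
        row: dict[str, object] = {"run": run, "role": p.role.value}
        for f, c in zip(factors, p.coded):
            row[f"coded_{f.name}"] = c
        for f, x in zip(factors, p.natural):
            row[f"natural_{f.name}"] = x
        rows.append(row)
    return pd.DataFrame(rows)


def write_design(factors: Sequence[FactorSpec], points: Sequence[DesignPoint], path) -> None:
    design_to_frame(factors, points).to_csv(path, index=False)
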