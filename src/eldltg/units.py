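"""Unit conversion and applicability bounds for lipid-panel analytes.

All internal computation in this package is done in mg/dl; SI (mmol/L)
values are converted at the I/O edges only, because the published
equation coefficients are stated on the mg/dl scale.

Conversion uses the standard molar factors: 38.67 mg/dl per mmol/L for
cholesterol-type analytes and 88.57 mg/dl per mmol/L for
triglyceride-type analytes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class Analyte(str, Enum):
    CHOLESTEROL = "cholesterol"
    TRIGLYCERIDE = "triglyceride"


class Unit(str, Enum):
    MG_DL = "mg/dl"
    MMOL_L = "mmol/L"


#: mg/dl per mmol/L, by analyte class
MG_PER_MMOL = {
    Analyte.CHOLESTEROL: 38.67,
    Analyte.TRIGLYCERIDE: 88.57,
}

#: Applicability bounds of the LDL-TG estimating equation (mg/dl).
#: Values at or above the bound are out of range (strict "<" applies).
TG_LIMIT_MG_DL = 1000.0
NONHDL_LIMIT_MG_DL = 400.0

#: Domain bound of the Sampson/NIH LDL-C equation (mg/dl).
SAMPSON_TG_LIMIT_MG_DL = 800.0


class Reason(str, Enum):
    """Why a value is out of range or could not be computed."""

    TG_OVER_LIMIT = "TG_OVER_LIMIT"
    NONHDL_OVER_LIMIT = "NONHDL_OVER_LIMIT"
    NONPOSITIVE_HDL = "NONPOSITIVE_HDL"
    NONPOSITIVE_NONHDL = "NONPOSITIVE_NONHDL"
    NONPOSITIVE_TG = "NONPOSITIVE_TG"
    MISSING_INPUT = "MISSING_INPUT"
    # used by derived markers only (e.g. negative remnant cholesterol)
    IMPLAUSIBLE = "IMPLAUSIBLE"


@dataclass(frozen=True)
class ValidityFlag:
    """Range/validity status of a computed marker.

    ``in_range`` is true exactly when ``reasons`` is empty.
    """

    reasons: tuple[Reason, ...] = field(default_factory=tuple)

    @property
    def in_range(self) -> bool:
        return len(self.reasons) == 0

    def __bool__(self) -> bool:  # truthy == usable without caveats
        return self.in_range


@dataclass(frozen=True)
class Concentration:
    """A single analyte concentration with declared units."""

    value: float
    analyte: Analyte
    unit: Unit = Unit.MG_DL

    def __post_init__(self) -> None:
        self_analyte = Analyte(self.analyte)
        self_unit = Unit(self.unit)
        object.__setattr__(self, "analyte", self_analyte)
        object.__setattr__(self, "unit", self_unit)
        if self.value is not None and not math.isnan(self.value) and self.value < 0:
            raise ValueError(f"concentration must be non-negative, got {self.value}")

    def to(self, target_unit: Unit | str) -> "Concentration":
        return convert(self, target_unit)


def convert(c: Concentration, target_unit: Unit | str) -> Concentration:
    """Convert a :class:`Concentration` between mg/dl and mmol/L.

    Converting to the unit the value is already expressed in is the
    identity; a round trip returns the input to within 1e-12 relative.
    """
    target = Unit(target_unit)
    if target == c.unit:
        return c
    factor = MG_PER_MMOL[c.analyte]
    if c.unit == Unit.MG_DL and target == Unit.MMOL_L:
        return Concentration(c.value / factor, c.analyte, target)
    return Concentration(c.value * factor, c.analyte, target)


def mgdl_to_mmoll(value: float, analyte: Analyte | str) -> float:
    return value / MG_PER_MMOL[Analyte(analyte)]


def mmoll_to_mgdl(value: float, analyte: Analyte | str) -> float:
    return value * MG_PER_MMOL[Analyte(analyte)]


def round_sig(x: float, digits: int = 3) -> float:
    """Round to a number of significant figures (for display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def si_display(value_mgdl: float, analyte: Analyte | str) -> float:
    """mmol/L equivalent rounded to 2 decimals, the package's display rule."""
    return round(mgdl_to_mmoll(value_mgdl, analyte), 2)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def check_validity(tg, nonhdl, hdl) -> ValidityFlag:
    """Check the estimating equation's applicability bounds.

    Inputs are mg/dl scalars (floats or None). The equation is
    restricted to TG < 1,000 mg/dl and nonHDL-C < 400 mg/dl; the
    reciprocal and ratio terms additionally require HDL-C > 0 and
    nonHDL-C > 0. Missing inputs yield a MISSING_INPUT reason rather
    than an exception.
    """
    reasons: list[Reason] = []
    if any(_is_missing(v) for v in (tg, nonhdl, hdl)):
        reasons.append(Reason.MISSING_INPUT)
    if not _is_missing(tg) and tg >= TG_LIMIT_MG_DL:
        reasons.append(Reason.TG_OVER_LIMIT)
    if not _is_missing(nonhdl) and nonhdl >= NONHDL_LIMIT_MG_DL:
        reasons.append(Reason.NONHDL_OVER_LIMIT)
    if not _is_missing(hdl) and hdl <= 0:
        reasons.append(Reason.NONPOSITIVE_HDL)
    if not _is_missing(nonhdl) and nonhdl <= 0:
        reasons.append(Reason.NONPOSITIVE_NONHDL)
    return ValidityFlag(tuple(reasons))
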