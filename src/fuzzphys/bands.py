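"""Crisp clinical banding of single vitals, blood glucose, and blood pressure.

These are the reference categorizations the fuzzy engine's membership
functions are built around: each of the eight vitals maps to Low / Normal /
High with the cut points themselves belonging to Normal (the Low and High
columns are strict inequalities), and blood glucose maps to the standard
four diagnostic categories with prandial-state-specific cut-offs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping

from .engine import Parameter, ReferenceRange, default_ranges
from .errors import InvalidInputError

__all__ = [
    "Band",
    "GlucoseState",
    "GlucoseCategory",
    "GlucoseReading",
    "BPBands",
    "classify_parameter",
    "classify_glucose",
    "classify_bp",
    "GLUCOSE_CUTS",
]


class Band(str, enum.Enum):
    LOW = "Low"
    NORMAL = "Normal"
    HIGH = "High"


class GlucoseState(str, enum.Enum):
    FASTING = "fasting"
    POST_MEAL = "post_meal"


class GlucoseCategory(str, enum.Enum):
    HYPOGLYCEMIA = "hypoglycemia"
    NORMAL = "normal"
    PRE_DIABETES = "pre_diabetes"
    DIABETES = "diabetes"


#: (hypo_below, prediabetes_from, diabetes_above) in mg/dL per prandial state.
#: Fasting: <70 hypo, 70-99 normal, 100-125 pre-diabetes, >125 diabetes.
#: Post-meal: <70 hypo, 70-139 normal, 140-199 pre-diabetes, >199 diabetes.
#: Values falling in the printed gaps (e.g. fasting 99.5) are Normal.
GLUCOSE_CUTS: dict[GlucoseState, tuple[float, float, float]] = {
    GlucoseState.FASTING: (70.0, 100.0, 125.0),
    GlucoseState.POST_MEAL: (70.0, 140.0, 199.0),
}


@dataclass(frozen=True)
class GlucoseReading:
    """One blood-glucose measurement in mg/dL with its prandial state."""

    value: float
    state: GlucoseState
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", GlucoseState(self.state))
        if not math.isfinite(self.value) or self.value <= 0:
            raise InvalidInputError(
                f"glucose must be a positive finite mg/dL value, got {self.value!r}"
            )


@dataclass(frozen=True)
class BPBands:
    """Component and overall blood-pressure bands."""

    systolic: Band
    diastolic: Band
    overall: Band


def classify_parameter(
    parameter: Parameter | str,
    value: float,
    ranges: Mapping[Parameter, ReferenceRange] | None = None,
) -> Band:
    """Crisp Low/Normal/High band of one parameter value.

    Cut points are inclusive to Normal (Low and High are strict).
    """
    try:
        parameter = Parameter(parameter) if not isinstance(parameter, Parameter) else parameter
    except ValueError:
        raise InvalidInputError(f"unknown parameter {parameter!r}") from None
    if not math.isfinite(value):
        raise InvalidInputError(f"cannot classify non-finite value {value!r}")
    if ranges is None:
        ranges = default_ranges()
    r = ranges[parameter]
    if value < r.low_cut:
        return Band.LOW
    if value > r.high_cut:
        return Band.HIGH
    return Band.NORMAL


def classify_glucose(reading: GlucoseReading) -> GlucoseCategory:
    """Diagnostic glucose category under the reading's prandial state."""
    hypo, pre_from, diab_above = GLUCOSE_CUTS[reading.state]
    v = reading.value
    if v < hypo:
        return GlucoseCategory.HYPOGLYCEMIA
    if v > diab_above:
        return GlucoseCategory.DIABETES
    if v >= pre_from:
        return GlucoseCategory.PRE_DIABETES
    return GlucoseCategory.NORMAL


def classify_bp(
    sbp: float,
    dbp: float,
    ranges: Mapping[Parameter, ReferenceRange] | None = None,
) -> BPBands:
    """Band each blood-pressure component and combine them.

    The overall band is High if either component is High, Low if either is
    Low and neither is High, otherwise Normal.
    """
    if not (math.isfinite(sbp) and math.isfinite(dbp)):
        raise InvalidInputError("blood pressures must be finite")
    if not (sbp > dbp > 0):
        raise InvalidInputError(
            f"need systolic > diastolic > 0, got ({sbp}, {dbp})"
        )
    sys_band = classify_parameter(Parameter.SBP, sbp, ranges)
    dia_band = classify_parameter(Parameter.DBP, dbp, ranges)
    if Band.HIGH in (sys_band, dia_band):
        overall = Band.HIGH
    elif Band.LOW in (sys_band, dia_band):
        overall = Band.LOW
    else:
        overall = Band.NORMAL
    return BPBands(systolic=sys_band, diastolic=dia_band, overall=overall)
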