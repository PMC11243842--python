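"""Fuzzy inference engine for three-level stress assessment.

Eight physiological parameters (heart rate, pulse-rate variability,
respiratory rate, SpO2, galvanic skin response, body temperature, and
systolic/diastolic blood pressure) are fuzzified against Low/Normal/High
reference bands, three rules map the banded degrees onto the stress states
Calm / Normal / Stressed, and a weighted average of the rule consequents
(1, 2, 3) yields a continuous stress score in [1, 3].

Membership shapes are the classic right-shoulder trapezoid for Low, a
left-shoulder trapezoid for High, and a triangle for Normal, built around
the crisp band cut points with a configurable transition half-width so the
engine degenerates to the crisp bands as the half-width goes to zero.

GSR is expressed as skin *resistance* in kOhm, so stress (sweating) drives
it low; the Stressed rule therefore matches Low(GSR) and the Calm rule
High(GSR).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping

from .errors import (
    DegenerateInferenceError,
    IncompleteSampleError,
    InvalidInputError,
)

__all__ = [
    "Parameter",
    "StressLabel",
    "ReferenceRange",
    "PhysioSample",
    "MembershipDegrees",
    "RuleActivations",
    "StressAssessment",
    "EngineConfig",
    "CRISP_CUTS",
    "default_ranges",
    "fuzzify",
    "fuzzify_sample",
    "activate_rules",
    "defuzzify",
    "assess",
]


class Parameter(str, enum.Enum):
    """The eight monitored physiological parameters."""

    HR = "hr"        # heart rate, beats/min
    PRV = "prv"      # pulse-rate variability (RMSSD), ms
    RR = "rr"        # respiratory rate, breaths/min
    SPO2 = "spo2"    # oxygen saturation, %
    GSR = "gsr"      # galvanic skin response, kOhm (resistance)
    BT = "bt"        # body temperature, degrees C
    SBP = "sbp"      # systolic blood pressure, mmHg
    DBP = "dbp"      # diastolic blood pressure, mmHg


class StressLabel(enum.IntEnum):
    CALM = 1
    NORMAL = 2
    STRESSED = 3


#: Crisp Low/Normal/High cut points per parameter: Normal is
#: [low_cut, high_cut] inclusive, Low strictly below, High strictly above.
#: The body-temperature normal band is taken to start at 36.5 degC, matching
#: its Low cut.
CRISP_CUTS: dict[Parameter, tuple[float, float]] = {
    Parameter.HR: (60.0, 90.0),
    Parameter.PRV: (32.0, 77.0),
    Parameter.RR: (12.0, 18.0),
    Parameter.SPO2: (97.0, 99.0),
    Parameter.GSR: (30.0, 50.0),
    Parameter.BT: (36.5, 37.5),
    Parameter.SBP: (90.0, 120.0),
    Parameter.DBP: (60.0, 80.0),
}

_SPO2_CEILING = 100.0


@dataclass(frozen=True)
class ReferenceRange:
    """Low/Normal/High band boundaries for one parameter.

    ``transition_halfwidth`` (delta) is the half-width, in parameter units,
    of the linear transition that the membership functions place around each
    crisp cut; delta = 0 reproduces the crisp bands exactly.
    """

    parameter: Parameter
    low_cut: float
    high_cut: float
    transition_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if not (self.low_cut < self.high_cut):
            raise InvalidInputError(
                f"{self.parameter}: low_cut {self.low_cut} must be below "
                f"high_cut {self.high_cut}"
            )
        if self.transition_halfwidth < 0:
            raise InvalidInputError("transition_halfwidth must be >= 0")
        if self.transition_halfwidth >= (self.high_cut - self.low_cut) / 2:
            raise InvalidInputError(
                f"{self.parameter}: transition_halfwidth "
                f"{self.transition_halfwidth} must be below half the normal "
                f"band width {(self.high_cut - self.low_cut) / 2}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low_cut + self.high_cut)


def default_ranges(transition_fraction: float = 0.10) -> dict[Parameter, ReferenceRange]:
    """Build the reference-range table from the crisp cuts.

    Each parameter's transition half-width is ``transition_fraction`` of its
    normal band width.  SpO2's upper transition is clipped so no membership
    vertex exceeds the physical ceiling of 100%.
    """
    if not (0 <= transition_fraction < 0.5):
        raise InvalidInputError("transition_fraction must lie in [0, 0.5)")
    table = {}
    for param, (lo, hi) in CRISP_CUTS.items():
        delta = transition_fraction * (hi - lo)
        if param is Parameter.SPO2:
            delta = min(delta, _SPO2_CEILING - hi)
        table[param] = ReferenceRange(param, lo, hi, delta)
    return table


@dataclass(frozen=True)
class PhysioSample:
    """One timestamped eight-parameter observation for one subject."""

    subject_id: str
    timestamp: datetime
    hr: float
    prv: float
    rr: float
    spo2: float
    gsr: float
    bt: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        for p in Parameter:
            v = self.value(p)
            if not math.isfinite(v):
                raise InvalidInputError(f"{p.value} must be finite, got {v!r}")
        if self.spo2 > 100.0:
            raise InvalidInputError(f"spo2 must be <= 100, got {self.spo2}")
        if self.gsr < 0.0:
            raise InvalidInputError(f"gsr must be >= 0, got {self.gsr}")
        if self.sbp <= self.dbp:
            raise InvalidInputError(
                f"systolic pressure {self.sbp} must exceed diastolic {self.dbp}"
            )

    def value(self, parameter: Parameter) -> float:
        return float(getattr(self, parameter.value))


@dataclass(frozen=True)
class MembershipDegrees:
    """Low/Normal/High membership degrees of one value, each in [0, 1]."""

    low: float
    normal: float
    high: float


@dataclass(frozen=True)
class RuleActivations:
    """Activation strengths of the Calm (r1), Normal (r2), Stressed (r3) rules."""

    r1: float
    r2: float
    r3: float


@dataclass(frozen=True)
class StressAssessment:
    """Continuous stress score in [1, 3] with its discrete label.

    ``degenerate`` is True when all three rule activations were zero and the
    fallback policy supplied the Normal midpoint instead of Eq-style
    defuzzification.
    """

    score: float
    label: StressLabel
    degenerate: bool = False


class TNorm(str, enum.Enum):
    MIN = "min"
    PRODUCT = "product"
    MEAN = "mean"


class DegeneratePolicy(str, enum.Enum):
    ERROR = "error"
    FALLBACK_NORMAL = "fallback_normal"


@dataclass(frozen=True)
class EngineConfig:
    """Tunable engine behaviour.

    tnorm
        Conjunction used to aggregate the eight antecedent degrees of each
        rule.  ``mean`` (default) keeps graded activations even when single
        parameters conflict; ``min`` and ``product`` are the strict t-norms.
    transition_fraction
        Membership transition half-width as a fraction of each parameter's
        normal band width.
    degenerate_policy
        What to do when every rule activation is zero: fall back to the
        Normal midpoint (flagged) or raise.
    t_low, t_high
        Score thresholds mapping the continuous score onto labels; scores on
        a threshold are assigned to Normal.
    """

    tnorm: TNorm = TNorm.MEAN
    transition_fraction: float = 0.10
    degenerate_policy: DegeneratePolicy = DegeneratePolicy.FALLBACK_NORMAL
    t_low: float = 1.5
    t_high: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "tnorm", TNorm(self.tnorm))
        object.__setattr__(
            self, "degenerate_policy", DegeneratePolicy(self.degenerate_policy)
        )
        if not (0 < self.transition_fraction < 0.5):
            raise InvalidInputError("transition_fraction must lie in (0, 0.5)")
        if not (1.0 < self.t_low < self.t_high < 3.0):
            raise InvalidInputError(
                f"need 1 < t_low < t_high < 3, got ({self.t_low}, {self.t_high})"
            )


DEFAULT_CONFIG = EngineConfig()


# --------------------------------------------------------------------------
# Fuzzification
# --------------------------------------------------------------------------

def _ramp_down(v: float, centre: float, delta: float) -> float:
    """1 below centre-delta, linear to 0 at centre+delta (crisp step if delta=0)."""
    if delta == 0.0:
        return 1.0 if v < centre else 0.0
    return min(1.0, max(0.0, (centre + delta - v) / (2.0 * delta)))


def fuzzify(value: float, range_: ReferenceRange) -> MembershipDegrees:
    """Low/Normal/High membership degrees of a single parameter value.

    Low is a right-shoulder trapezoid saturating below ``low_cut - delta``,
    High is its mirror around ``high_cut``, and Normal is a triangle with
    apex at the normal-band midpoint and feet at ``low_cut - delta`` and
    ``high_cut + delta``.
    """
    if not math.isfinite(value):
        raise InvalidInputError(f"cannot fuzzify non-finite value {value!r}")
    delta = range_.transition_halfwidth
    low = _ramp_down(value, range_.low_cut, delta)
    high = 1.0 - _ramp_down(value, range_.high_cut, delta)

    apex = range_.midpoint
    left_foot = range_.low_cut - delta
    right_foot = range_.high_cut + delta
    if value <= left_foot or value >= right_foot:
        normal = 0.0
    elif value <= apex:
        normal = (value - left_foot) / (apex - left_foot)
    else:
        normal = (right_foot - value) / (right_foot - apex)
    return MembershipDegrees(low=low, normal=min(1.0, normal), high=high)


def fuzzify_sample(
    sample: PhysioSample, ranges: Mapping[Parameter, ReferenceRange]
) -> dict[Parameter, MembershipDegrees]:
    return {p: fuzzify(sample.value(p), ranges[p]) for p in Parameter}


# --------------------------------------------------------------------------
# Rule evaluation
# --------------------------------------------------------------------------

# Antecedent band per parameter for each rule.  Calm pairs low circulatory /
# respiratory drive with high oxygenation, high skin resistance (dry skin)
# and high peripheral temperature; Stressed is the mirror image.
_CALM_PATTERN: dict[Parameter, str] = {
    Parameter.HR: "low",
    Parameter.PRV: "low",
    Parameter.RR: "low",
    Parameter.SPO2: "high",
    Parameter.GSR: "high",
    Parameter.BT: "high",
    Parameter.SBP: "low",
    Parameter.DBP: "low",
}
_STRESSED_PATTERN: dict[Parameter, str] = {
    p: {"low": "high", "high": "low"}[band] for p, band in _CALM_PATTERN.items()
}

RULE_PATTERNS: dict[StressLabel, dict[Parameter, str]] = {
    StressLabel.CALM: _CALM_PATTERN,
    StressLabel.NORMAL: {p: "normal" for p in Parameter},
    StressLabel.STRESSED: _STRESSED_PATTERN,
}


def _aggregate(degrees: list[float], tnorm: TNorm) -> float:
    if tnorm is TNorm.MIN:
        return min(degrees)
    if tnorm is TNorm.PRODUCT:
        out = 1.0
        for d in degrees:
            out *= d
        return out
    return sum(degrees) / len(degrees)


def activate_rules(
    degrees: Mapping[Parameter, MembershipDegrees],
    config: EngineConfig = DEFAULT_CONFIG,
) -> RuleActivations:
    """Evaluate the Calm / Normal / Stressed rules on a fuzzified sample."""
    missing = [p.value for p in Parameter if p not in degrees]
    if missing:
        raise IncompleteSampleError(
            f"membership degrees missing for: {', '.join(missing)}"
        )
    acts = {}
    for label, pattern in RULE_PATTERNS.items():
        antecedents = [getattr(degrees[p], pattern[p]) for p in Parameter]
        acts[label] = _aggregate(antecedents, config.tnorm)
    return RuleActivations(
        r1=acts[StressLabel.CALM],
        r2=acts[StressLabel.NORMAL],
        r3=acts[StressLabel.STRESSED],
    )


# --------------------------------------------------------------------------
# Defuzzification
# --------------------------------------------------------------------------

def _label_for(score: float, config: EngineConfig) -> StressLabel:
    if score < config.t_low:
        return StressLabel.CALM
    if score > config.t_high:
        return StressLabel.STRESSED
    return StressLabel.NORMAL


def defuzzify(
    acts: RuleActivations,
    config: EngineConfig = DEFAULT_CONFIG,
    context: str = "",
) -> StressAssessment:
    """Weighted average of the rule consequents 1, 2, 3.

    score = (r1*1 + r2*2 + r3*3) / (r1 + r2 + r3)

    With all activations zero the score is undefined; the configured policy
    either raises or falls back to the Normal midpoint (score 2, flagged).
    """
    for name in ("r1", "r2", "r3"):
        v = getattr(acts, name)
        if not (0.0 <= v <= 1.0):
            raise InvalidInputError(f"activation {name}={v} outside [0, 1]")
    denom = acts.r1 + acts.r2 + acts.r3
    if denom == 0.0:
        if config.degenerate_policy is DegeneratePolicy.ERROR:
            raise DegenerateInferenceError(
                "all rule activations are zero"
                + (f" for sample {context}" if context else "")
            )
        return StressAssessment(score=2.0, label=StressLabel.NORMAL, degenerate=True)
    score = (acts.r1 * 1.0 + acts.r2 * 2.0 + acts.r3 * 3.0) / denom
    # the weighted average lies in [1, 3] mathematically; guard FP round-off
    score = min(3.0, max(1.0, score))
    return StressAssessment(score=score, label=_label_for(score, config))


def assess(
    sample: PhysioSample,
    ranges: Mapping[Parameter, ReferenceRange] | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> StressAssessment:
    """Full pipeline: fuzzify all eight parameters, fire the rules, defuzzify."""
    if ranges is None:
        ranges = default_ranges(config.transition_fraction)
    degrees = fuzzify_sample(sample, ranges)
    acts = activate_rules(degrees, config)
    return defuzzify(acts, config, context=f"{sample.subject_id}@{sample.timestamp}")
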