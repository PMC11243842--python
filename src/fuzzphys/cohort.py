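"""Synthetic diabetic-cohort simulator.

Generates a study-like cohort (128 volunteers, 68 male / 60 female, ages
truncated-normal 42 +/- 17 on 12-75 years) and, per subject, a five-day
acquisition series with four phases per day: after breakfast (~40 min
post-meal, when digestion has raised glucose), after the morning medication
has taken effect (~60 min post-dose, when glucose has fallen), before
lunch, and after lunch.

Each record carries a latent stress class (Calm / Normal / Stressed).  The
eight vitals are drawn around the band targets their rule direction
dictates — e.g. a Stressed record has HR above 90 bpm and GSR (skin
resistance) below 30 kOhm — perturbed by per-parameter Gaussian noise.
Glucose couples positively to stress, and blood pressure couples positively
to both stress and the glucose excursion, reproducing the positive
pairwise correlations the protocol is designed to expose.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bands import GlucoseReading, GlucoseState
from .engine import (
    CRISP_CUTS,
    DEFAULT_CONFIG,
    EngineConfig,
    Parameter,
    PhysioSample,
    ReferenceRange,
    RULE_PATTERNS,
    StressLabel,
    assess,
)
from .errors import InvalidInputError
from .metrics import confusion, per_class_metrics

__all__ = [
    "Phase",
    "CohortSpec",
    "Subject",
    "ProtocolRecord",
    "DEFAULT_NOISE_SD",
    "generate_cohort",
    "generate_series",
    "generate_dataset",
    "label_recovery_experiment",
]


class Phase(str, enum.Enum):
    """The four daily acquisition phases, in clock order."""

    POST_MEAL_1 = "post_meal_1"      # ~40 min after breakfast
    POST_MEDICATION = "post_medication"  # ~60 min after the morning dose
    PRE_MEAL = "pre_meal"            # before lunch (fasting-like)
    POST_MEAL_2 = "post_meal_2"      # ~40 min after lunch


#: Minutes after 00:00 of each phase's acquisition.  Breakfast at 08:00 and
#: the meal-response latency of ~40 min place the first acquisition at
#: 08:40; the 09:00 dose plus the ~60 min onset places the second at 10:00;
#: the pre-lunch acquisition is at 12:30 and the post-lunch one 40 min
#: after the 13:00 meal.
PHASE_CLOCK_MIN: dict[Phase, int] = {
    Phase.POST_MEAL_1: 8 * 60 + 40,
    Phase.POST_MEDICATION: 10 * 60,
    Phase.PRE_MEAL: 12 * 60 + 30,
    Phase.POST_MEAL_2: 13 * 60 + 40,
}

#: Glucose excursion (mg/dL) from baseline at each phase in the noiseless,
#: uncoupled limit: the full meal rise at the two post-meal acquisitions, a
#: net fall once the medication is in full effect (residual meal rise minus
#: the dose effect), and none before lunch.
def _phase_glucose_effect(phase: Phase, meal_rise: float, med_drop: float) -> float:
    if phase in (Phase.POST_MEAL_1, Phase.POST_MEAL_2):
        return meal_rise
    if phase is Phase.POST_MEDICATION:
        return 0.35 * meal_rise - med_drop
    return 0.0


DEFAULT_NOISE_SD: dict[Parameter, float] = {
    Parameter.HR: 3.0,     # beats/min
    Parameter.PRV: 4.0,    # ms
    Parameter.RR: 0.8,     # breaths/min
    Parameter.SPO2: 0.3,   # %
    Parameter.GSR: 2.0,    # kOhm
    Parameter.BT: 0.1,     # degC
    Parameter.SBP: 3.0,    # mmHg
    Parameter.DBP: 2.0,    # mmHg
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; the defaults reproduce the study conditions."""

    n_subjects: int = 128
    n_male: int = 68
    age_mean: float = 42.0
    age_sd: float = 17.0
    age_range: tuple[float, float] = (12.0, 75.0)
    stress_glucose_coupling: float = 15.0   # mg/dL per stress level step
    stress_bp_coupling: float = 5.0         # mmHg per stress level step
    glucose_bp_coupling: float = 0.08       # mmHg per mg/dL glucose excursion
    noise_sd: Mapping[Parameter, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    glucose_noise_sd: float = 5.0           # mg/dL
    class_prevalence: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    meal_rise: float = 60.0                 # mg/dL peak post-meal excursion
    med_drop: float = 50.0                  # mg/dL medication effect at onset
    n_days: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_subjects):
            raise InvalidInputError("n_subjects must be positive")
        if not (0 <= self.n_male <= self.n_subjects):
            raise InvalidInputError("need 0 <= n_male <= n_subjects")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise InvalidInputError("age_range must lie within [0, 120]")
        if abs(sum(self.class_prevalence) - 1.0) > 1e-9 or min(self.class_prevalence) < 0:
            raise InvalidInputError("class_prevalence must be a probability vector")
        noise = {Parameter(k): float(v) for k, v in dict(self.noise_sd).items()}
        missing = [p for p in Parameter if p not in noise]
        if missing:
            raise InvalidInputError(f"noise_sd missing parameters: {missing}")
        object.__setattr__(self, "noise_sd", noise)

    def scaled_noise(self, factor: float) -> "CohortSpec":
        """Copy of the spec with every noise level multiplied by ``factor``."""
        return replace(
            self,
            noise_sd={p: v * factor for p, v in self.noise_sd.items()},
            glucose_noise_sd=self.glucose_noise_sd * factor,
        )


@dataclass(frozen=True)
class Subject:
    subject_id: str
    tag_number: str
    index: int
    sex: str                 # 'M' or 'F'
    age: float               # years
    baseline_glucose: float  # fasting mg/dL
    bp_offset: float         # subject-level mmHg shift applied to both components


@dataclass(frozen=True)
class ProtocolRecord:
    """One acquisition: vitals + glucose + ground-truth stress class."""

    subject_id: str
    day: int
    phase: Phase
    timestamp: datetime
    sample: PhysioSample
    glucose: GlucoseReading
    latent_stress: StressLabel


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[Subject]:
    """Draw the cohort: exact sex split, truncated-normal ages, baselines.

    Baseline fasting glucose is drawn uniformly over 75-170 mg/dL so the
    cohort spans the normal, pre-diabetic and diabetic fasting bands.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd,
        size=spec.n_subjects, random_state=rng,
    )
    sexes = np.array(["M"] * spec.n_male + ["F"] * (spec.n_subjects - spec.n_male))
    rng.shuffle(sexes)
    baseline_glucose = rng.uniform(75.0, 170.0, spec.n_subjects)
    bp_offsets = rng.uniform(-3.0, 3.0, spec.n_subjects)
    return [
        Subject(
            subject_id=f"S{i + 1:04d}",
            tag_number=f"TAG{i + 1:04d}",
            index=i,
            sex=str(sexes[i]),
            age=float(ages[i]),
            baseline_glucose=float(baseline_glucose[i]),
            bp_offset=float(bp_offsets[i]),
        )
        for i in range(spec.n_subjects)
    ]


# Band target offsets, as fractions of the normal band width, used when a
# rule direction places a parameter below/above its cuts: far enough past
# the cut that the membership transition is saturated at the default
# transition fraction.
_BAND_MARGIN = 0.25


def _band_target(param: Parameter, direction: str) -> float:
    lo, hi = CRISP_CUTS[param]
    width = hi - lo
    if direction == "low":
        return lo - _BAND_MARGIN * width
    if direction == "high":
        target = hi + _BAND_MARGIN * width
        return min(target, 99.8) if param is Parameter.SPO2 else target
    return 0.5 * (lo + hi)


def generate_series(subject: Subject, spec: CohortSpec = CohortSpec()) -> list[ProtocolRecord]:
    """Five days x four phases of coupled vitals/glucose/BP for one subject."""
    rng = np.random.default_rng((spec.seed, 1000003 + subject.index))
    start = datetime(2024, 3, 4, tzinfo=timezone.utc)  # arbitrary study Monday
    labels = [StressLabel.CALM, StressLabel.NORMAL, StressLabel.STRESSED]
    records: list[ProtocolRecord] = []
    for day in range(1, spec.n_days + 1):
        for phase in Phase:
            latent = labels[rng.choice(3, p=spec.class_prevalence)]
            stress_dev = latent.value - 2  # -1, 0, +1

            glucose_dev = (
                _phase_glucose_effect(phase, spec.meal_rise, spec.med_drop)
                + spec.stress_glucose_coupling * stress_dev
                + rng.normal(0.0, spec.glucose_noise_sd)
            )
            glucose_value = max(40.0, subject.baseline_glucose + glucose_dev)

            pattern = RULE_PATTERNS[latent]
            values: dict[Parameter, float] = {}
            for param in Parameter:
                v = _band_target(param, pattern[param])
                v += rng.normal(0.0, spec.noise_sd[param])
                if param is Parameter.SPO2:
                    v = min(v, 100.0)
                elif param is Parameter.GSR:
                    v = max(v, 0.0)
                values[param] = v
            bp_shift = (
                subject.bp_offset
                + spec.stress_bp_coupling * stress_dev
                + spec.glucose_bp_coupling * (glucose_value - subject.baseline_glucose)
            )
            values[Parameter.SBP] += bp_shift
            values[Parameter.DBP] += bp_shift
            if values[Parameter.DBP] >= values[Parameter.SBP]:
                values[Parameter.DBP] = values[Parameter.SBP] - 5.0

            ts = start + timedelta(days=day - 1, minutes=PHASE_CLOCK_MIN[phase])
            sample = PhysioSample(
                subject_id=subject.subject_id,
                timestamp=ts,
                **{p.value: values[p] for p in Parameter},
            )
            state = (
                GlucoseState.FASTING if phase is Phase.PRE_MEAL
                else GlucoseState.POST_MEAL
            )
            records.append(
                ProtocolRecord(
                    subject_id=subject.subject_id,
                    day=day,
                    phase=phase,
                    timestamp=ts,
                    sample=sample,
                    glucose=GlucoseReading(value=glucose_value, state=state, timestamp=ts),
                    latent_stress=latent,
                )
            )
    return records


def generate_dataset(spec: CohortSpec = CohortSpec()) -> list[ProtocolRecord]:
    """Cohort plus all per-subject series, flattened."""
    records: list[ProtocolRecord] = []
    for subject in generate_cohort(spec):
        records.extend(generate_series(subject, spec))
    return records


# --------------------------------------------------------------------------
# Label-recovery harness
# --------------------------------------------------------------------------

def label_recovery_experiment(
    spec: CohortSpec = CohortSpec(),
    config: EngineConfig = DEFAULT_CONFIG,
    ranges: Mapping[Parameter, ReferenceRange] | None = None,
    records: Sequence[ProtocolRecord] | None = None,
) -> dict:
    """Score the fuzzy engine against the generator's latent classes.

    Returns overall accuracy, per-class recall (the probability a latent
    class is recovered), the confusion matrix, and the full per-class
    one-vs-rest metric table.
    """
    if records is None:
        records = generate_dataset(spec)
    truth = [r.latent_stress.name.capitalize() for r in records]
    predicted = [
        assess(r.sample, ranges=ranges, config=config).label.name.capitalize()
        for r in records
    ]
    cm = confusion(truth, predicted)
    diag = np.diag(cm.counts)
    row_totals = cm.counts.sum(axis=1)
    per_class_accuracy = {
        label: (float(diag[i] / row_totals[i]) if row_totals[i] else float("nan"))
        for i, label in enumerate(cm.labels)
    }
    return {
        "n_records": len(records),
        "overall_accuracy": float(np.trace(cm.counts) / cm.counts.sum()),
        "per_class_recall": per_class_accuracy,
        "confusion_matrix": cm,
        "metrics": per_class_metrics(cm),
    }
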