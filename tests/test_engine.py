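"""Fuzzy engine: membership shapes, rule firing, defuzzification, assessment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzphys.bands import classify_parameter
from fuzzphys.engine import (
    CRISP_CUTS,
    DEFAULT_CONFIG,
    EngineConfig,
    MembershipDegrees,
    Parameter,
    ReferenceRange,
    RuleActivations,
    RULE_PATTERNS,
    StressLabel,
    activate_rules,
    assess,
    default_ranges,
    defuzzify,
    fuzzify,
    fuzzify_sample,
)
from fuzzphys.errors import (
    DegenerateInferenceError,
    IncompleteSampleError,
    InvalidInputError,
)

from conftest import make_sample

HR_RANGE = ReferenceRange(Parameter.HR, 60.0, 90.0, 3.0)


def oracle_memberships(value, range_):
    """Independent piecewise-linear membership oracle built on np.interp."""
    lo, hi, d = range_.low_cut, range_.high_cut, range_.transition_halfwidth
    mid = 0.5 * (lo + hi)
    return (
        float(np.interp(value, [lo - d, lo + d], [1.0, 0.0])),
        float(np.interp(value, [lo - d, mid, hi + d], [0.0, 1.0, 0.0])),
        float(np.interp(value, [hi - d, hi + d], [0.0, 1.0])),
    )


class TestFuzzify:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (75.0, (0.0, 1.0, 0.0)),   # apex of the Normal triangle
            (60.0, (0.5, 1 / 6, 0.0)),  # midpoint of the Low transition
            (57.0, (1.0, 0.0, 0.0)),   # left foot of the Normal triangle
            (58.0, (5 / 6, 1 / 18, 0.0)),
            (90.0, (0.0, 1 / 6, 0.5)),
            (120.0, (0.0, 0.0, 1.0)),
        ],
    )
    def test_hand_computed_degrees(self, value, expected):
        d = fuzzify(value, HR_RANGE)
        assert (d.low, d.normal, d.high) == pytest.approx(expected, abs=1e-12)

    @given(value=st.floats(min_value=-50.0, max_value=300.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_interp_oracle_and_invariants(self, value):
        d = fuzzify(value, HR_RANGE)
        assert (d.low, d.normal, d.high) == pytest.approx(
            oracle_memberships(value, HR_RANGE), abs=1e-12
        )
        degrees = [d.low, d.normal, d.high]
        assert all(0.0 <= x <= 1.0 for x in degrees)
        assert sum(x > 0 for x in degrees) <= 2

    def test_non_finite_value_rejected(self):
        with pytest.raises(InvalidInputError):
            fuzzify(float("nan"), HR_RANGE)
        with pytest.raises(InvalidInputError):
            fuzzify(float("inf"), HR_RANGE)

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ReferenceRange(Parameter.HR, 90.0, 60.0, 1.0)
        with pytest.raises(InvalidInputError):
            ReferenceRange(Parameter.HR, 60.0, 90.0, 20.0)  # >= half band width

    def test_spo2_transition_respects_ceiling(self):
        r = default_ranges(transition_fraction=0.49)[Parameter.SPO2]
        assert r.high_cut + r.transition_halfwidth <= 100.0


def constant_degrees(low=0.0, normal=0.0, high=0.0):
    return {p: MembershipDegrees(low, normal, high) for p in Parameter}


class TestActivateRules:
    @pytest.mark.parametrize("tnorm", ["min", "product", "mean"])
    def test_all_normal_fires_only_r2(self, tnorm):
        acts = activate_rules(
            constant_degrees(normal=1.0), EngineConfig(tnorm=tnorm)
        )
        assert (acts.r1, acts.r2, acts.r3) == (0.0, 1.0, 0.0)

    def test_saturated_calm_pattern_fires_r1(self):
        degrees = {
            p: (
                MembershipDegrees(1.0, 0.0, 0.0)
                if band == "low"
                else MembershipDegrees(0.0, 0.0, 1.0)
            )
            for p, band in RULE_PATTERNS[StressLabel.CALM].items()
        }
        for tnorm in ("min", "product", "mean"):
            acts = activate_rules(degrees, EngineConfig(tnorm=tnorm))
            assert acts.r1 == 1.0
            assert acts.r2 == 0.0
            assert acts.r3 == 0.0

    def test_mean_aggregation_is_arithmetic_mean(self):
        # fixed mixed sample: HR leans high, SpO2 leans low, rest normal
        degrees = constant_degrees(normal=1.0)
        degrees[Parameter.HR] = MembershipDegrees(0.0, 0.4, 0.6)
        degrees[Parameter.SPO2] = MembershipDegrees(0.8, 0.2, 0.0)
        acts = activate_rules(degrees, EngineConfig(tnorm="mean"))
        # hand sums over the eight antecedents of each rule
        assert acts.r1 == pytest.approx((0.0 + 0.0 + 6 * 0.0) / 8)
        assert acts.r2 == pytest.approx((0.4 + 0.2 + 6 * 1.0) / 8)
        assert acts.r3 == pytest.approx((0.6 + 0.8 + 6 * 0.0) / 8)

    def test_missing_parameter_rejected(self):
        degrees = constant_degrees(normal=1.0)
        del degrees[Parameter.GSR]
        with pytest.raises(IncompleteSampleError, match="gsr"):
            activate_rules(degrees)


class TestDefuzzify:
    def test_single_active_rule_pins_score(self):
        out = defuzzify(RuleActivations(1.0, 0.0, 0.0))
        assert out.score == 1.0 and out.label is StressLabel.CALM
        out = defuzzify(RuleActivations(0.0, 0.0, 0.7))
        assert out.score == pytest.approx(3.0, rel=1e-12)
        assert out.label is StressLabel.STRESSED

    @pytest.mark.parametrize("c", [1e-6, 0.25, 1.0])
    def test_equal_activations_give_exact_normal(self, c):
        out = defuzzify(RuleActivations(c, c, c))
        assert out.score == 2.0 and out.label is StressLabel.NORMAL

    def test_weighted_average_hand_value(self):
        out = defuzzify(RuleActivations(0.1, 0.2, 0.3))
        assert out.score == pytest.approx(7.0 / 3.0, rel=1e-12)
        assert out.label is StressLabel.NORMAL

    def test_degenerate_fallback_and_error_policies(self):
        out = defuzzify(RuleActivations(0.0, 0.0, 0.0))
        assert out.degenerate and out.score == 2.0
        strict = EngineConfig(degenerate_policy="error")
        with pytest.raises(DegenerateInferenceError, match="S0001"):
            defuzzify(RuleActivations(0.0, 0.0, 0.0), strict, context="S0001")

    def test_out_of_range_activation_rejected(self):
        with pytest.raises(InvalidInputError):
            defuzzify(RuleActivations(1.2, 0.0, 0.0))

    @given(
        r1=st.floats(0, 1), r2=st.floats(0, 1), r3=st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_score_bounded(self, r1, r2, r3):
        out = defuzzify(RuleActivations(r1, r2, r3))
        assert 1.0 <= out.score <= 3.0


STRESSED_SAMPLE = dict(
    hr=120, prv=100, rr=25, spo2=93, gsr=10, bt=35.5, sbp=140, dbp=95
)
CALM_SAMPLE = dict(
    hr=45, prv=20, rr=8, spo2=99.9, gsr=70, bt=38.5, sbp=80, dbp=50
)


class TestAssess:
    def test_midpoint_sample_is_exactly_normal(self, midpoint_sample):
        out = assess(midpoint_sample)
        assert out.score == 2.0 and out.label is StressLabel.NORMAL

    def test_saturated_stressed_sample(self):
        out = assess(make_sample(**STRESSED_SAMPLE))
        assert out.score == 3.0 and out.label is StressLabel.STRESSED

    def test_saturated_calm_sample(self):
        out = assess(make_sample(**CALM_SAMPLE))
        assert out.score == 1.0 and out.label is StressLabel.CALM

    def test_conflicting_sample_matches_independent_oracle(self, ranges):
        # HR/SBP/DBP push stressed, SpO2/GSR push calm, rest normal-ish
        sample = make_sample(hr=92, spo2=99.4, gsr=53, sbp=122, dbp=81)
        expected = {}
        for label, pattern in RULE_PATTERNS.items():
            antecedents = []
            for p in Parameter:
                low, normal, high = oracle_memberships(sample.value(p), ranges[p])
                antecedents.append({"low": low, "normal": normal, "high": high}[pattern[p]])
            expected[label] = sum(antecedents) / 8.0
        num = expected[StressLabel.CALM] + 2 * expected[StressLabel.NORMAL] + 3 * expected[StressLabel.STRESSED]
        den = sum(expected.values())
        out = assess(sample, ranges=ranges)
        assert out.score == pytest.approx(num / den, rel=1e-12)

    def test_monotone_in_hr_under_stress_saturation(self):
        scores = [
            assess(make_sample(**{**STRESSED_SAMPLE, "hr": hr})).score
            for hr in np.linspace(80, 100, 41)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_deterministic(self, midpoint_sample):
        a = assess(midpoint_sample)
        b = assess(midpoint_sample)
        assert a == b

    @pytest.mark.parametrize(
        "direction, values, expected_label",
        [
            ("low", CALM_SAMPLE, StressLabel.CALM),
            ("high", STRESSED_SAMPLE, StressLabel.STRESSED),
        ],
    )
    def test_crisp_limit_matches_band_classifier(self, direction, values, expected_label):
        """With a vanishing transition width, direction-consistent samples get
        the label their crisp bands dictate."""
        config = EngineConfig(transition_fraction=1e-9)
        ranges = default_ranges(transition_fraction=1e-9)
        sample = make_sample(**values)
        out = assess(sample, ranges=ranges, config=config)
        assert out.label is expected_label
        # cross-check each parameter's crisp band against the rule pattern
        pattern = RULE_PATTERNS[expected_label]
        for p in Parameter:
            band = classify_parameter(p, sample.value(p))
            assert band.value.lower() == pattern[p]

    def test_invalid_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            make_sample(spo2=105)
        with pytest.raises(InvalidInputError):
            make_sample(sbp=80, dbp=90)
        with pytest.raises(InvalidInputError):
            make_sample(gsr=-1)
        with pytest.raises(InvalidInputError):
            make_sample(hr=float("nan"))

    @given(
        hr=st.floats(30, 200), prv=st.floats(1, 200), rr=st.floats(4, 40),
        spo2=st.floats(80, 100), gsr=st.floats(0, 120), bt=st.floats(34, 41),
        sbp=st.floats(61, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_random_samples_score_in_bounds(self, hr, prv, rr, spo2, gsr, bt, sbp):
        sample = make_sample(hr=hr, prv=prv, rr=rr, spo2=spo2, gsr=gsr, bt=bt,
                             sbp=sbp, dbp=sbp - 30 if sbp > 60 else 30)
        out = assess(sample)
        assert 1.0 <= out.score <= 3.0
        assert out.label in StressLabel
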