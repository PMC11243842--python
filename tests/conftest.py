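from datetime import datetime, timezone

import pytest

from fuzzphys.engine import CRISP_CUTS, Parameter, PhysioSample, default_ranges

TS = datetime(2024, 3, 4, 8, 40, tzinfo=timezone.utc)


def make_sample(**overrides) -> PhysioSample:
    """An eight-parameter sample, defaulting every vital to its normal-band midpoint."""
    values = {p.value: 0.5 * (lo + hi) for p, (lo, hi) in CRISP_CUTS.items()}
    values.update(overrides)
    return PhysioSample(subject_id="S0001", timestamp=TS, **values)


@pytest.fixture
def ranges():
    return default_ranges()


@pytest.fixture
def midpoint_sample():
    return make_sample()
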