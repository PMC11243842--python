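"""Exception hierarchy shared across the package."""


class FuzzphysError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FuzzphysError, ValueError):
    """A value violates a physiological or schema invariant."""


class IncompleteSampleError(FuzzphysError, ValueError):
    """A rule evaluation was attempted without all eight membership triples."""


class DegenerateInferenceError(FuzzphysError, ArithmeticError):
    """All rule activations were zero and the strict policy is in force."""


class InsufficientDataError(FuzzphysError, ValueError):
    """Too few beats or too short a signal for the requested estimate."""


class NoBeatsError(FuzzphysError, ValueError):
    """Peak detection found no usable beats (flat or empty signal)."""


class InvalidSignalError(FuzzphysError, ValueError):
    """A waveform violates a structural requirement (e.g. zero DC level)."""


class SchemaError(FuzzphysError, ValueError):
    """A record file failed validation; the message names field and line."""
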