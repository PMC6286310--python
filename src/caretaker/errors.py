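"""Exception hierarchy shared across the package."""


class CaretakerError(Exception):
    """Base class for all package errors."""


class CoordinateError(CaretakerError):
    """Invalid genomic coordinates (start > end, non-positive, outside arm)."""


class IntervalParseError(CaretakerError):
    """Malformed interval or sequence-change text."""


class AnnotationError(CaretakerError):
    """Inconsistent genome annotation (gene outside arm, unknown arm, ...)."""


class ConfigError(CaretakerError):
    """Invalid generator or simulation configuration."""


class InputError(CaretakerError):
    """Invalid measurement/statistics input (empty group, bad values, ...)."""


class SampleSizeError(InputError):
    """Sample too small for the requested statistical test."""


class EstimateError(CaretakerError):
    """A Monte-Carlo estimate could not be formed (e.g. no resolved runs)."""
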