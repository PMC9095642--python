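"""Exception hierarchy shared across the package."""


class GlycotrialError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GlycotrialError, ValueError):
    """A configuration object violates one of its invariants.

    The message always names the offending field.
    """


class DataError(GlycotrialError, ValueError):
    """An input table violates a structural contract (ordering, duplicates...)."""


class DomainError(GlycotrialError, ValueError):
    """A scalar input is outside the mathematical domain of an operation."""


class ImplausibleMeasurementError(GlycotrialError, ValueError):
    """A derived measurement is physiologically impossible (e.g. FFM >= weight).

    Raised instead of silently clipping so bad inputs surface in the pipeline.
    """


class InsufficientControlsError(GlycotrialError, RuntimeError):
    """The eligible control pool cannot supply the requested matching ratio."""


class DegenerateInputError(GlycotrialError, ValueError):
    """A statistical routine received a degenerate design (single group/class)."""
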