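"""Exception hierarchy shared across the package."""


class BlinkkitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BlinkkitError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(BlinkkitError, ValueError):
    """Not enough data to run the requested analysis."""


class DegenerateDataError(BlinkkitError, ValueError):
    """Data carry no usable signal (e.g. a flat titration curve)."""


class ComplexTitrationError(BlinkkitError, ValueError):
    """Titration has an interior extremum; a single-pKa fit is refused.

    Carries the pH of the interior maximum when known.
    """

    def __init__(self, message: str, extremum_ph: float | None = None):
        super().__init__(message)
        self.extremum_ph = extremum_ph


class SchemaError(BlinkkitError, ValueError):
    """A file or config does not match the expected schema."""
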