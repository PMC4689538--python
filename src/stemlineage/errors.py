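"""Exception types shared across the package."""


class StemLineageError(Exception):
    """Base class for package errors."""


class InvalidParameterError(StemLineageError, ValueError):
    """A parameter is outside its admissible range."""


class NoEquilibriumError(StemLineageError, RuntimeError):
    """No steady state was found in the search domain."""


class NumericalFailureError(StemLineageError, RuntimeError):
    """A numerical routine produced non-finite or unusable output."""


class NonHyperbolicError(StemLineageError, RuntimeError):
    """The linearized system is degenerate (Delta = 0 or B = 0): variances undefined."""


class DivergenceError(StemLineageError, RuntimeError):
    """A trajectory exceeded the configured state bound."""
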