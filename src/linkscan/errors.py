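"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A generator or analysis configuration violates its preconditions."""


class AlignmentError(ValueError):
    """An alignment or its metadata is malformed for the requested operation."""


class SaturationError(ValueError):
    """A distance transform was asked to operate outside its domain (p >= 1)."""


class IncomparablePairError(ValueError):
    """Two aligned sequences share no unambiguous, ungapped columns."""


class NoTransitionError(RuntimeError):
    """A melt curve shows no unfolding transition to extract a Tm from."""


class FitError(RuntimeError):
    """A nonlinear fit could not be performed on the given data."""
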