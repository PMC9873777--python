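"""Exception hierarchy shared across the package."""


class SorgsimError(Exception):
    """Base class for all package errors."""


class InvalidSampleError(SorgsimError):
    """A soil core sample violates its physical preconditions."""


class InvalidWeatherError(SorgsimError):
    """A weather record is inconsistent (e.g. tmax < tmin) or has gaps."""


class InvalidGenotypeError(SorgsimError):
    """A genotype parameter set violates its preconditions."""


class FitError(SorgsimError):
    """A regression or curve fit cannot be performed (singular design, ...)."""


class InputError(SorgsimError):
    """Bad user-supplied input (unknown preset, window outside coverage, ...)."""


class StateError(SorgsimError):
    """An operation was called in an invalid simulation state."""


class ClosureError(SorgsimError):
    """Internal invariant violation: a daily mass balance failed to close.

    This is a bug trap; it is never caught and swallowed inside the package.
    """
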