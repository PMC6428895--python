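"""Exception hierarchy shared across the package."""


class DepictiveError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DepictiveError, ValueError):
    """Input violates a documented precondition."""


class NonIdentifiableError(DepictiveError, ValueError):
    """The data cannot pin down the requested parameters.

    Raised e.g. when a dose-response curve shows no transition (all
    fractions ~0 or ~1) or when no dose exhibits partial killing.
    """


class SchemaError(DepictiveError, ValueError):
    """An event table is missing required columns or has malformed rows."""


class ConvergenceError(DepictiveError, RuntimeError):
    """A numerical routine failed to converge."""
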