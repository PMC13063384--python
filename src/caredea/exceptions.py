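"""Exception hierarchy.

Everything raised on bad user input derives from :class:`InvalidInputError`
(a ``ValueError``), so callers can catch one type at pipeline boundaries;
solver failures are runtime errors because they indicate a numerical
problem, not a data-validation problem.
"""


class CareDEAError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CareDEAError, ValueError):
    """Input violates a documented precondition."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(InvalidInputError):
    """Data degenerate for the requested statistic (e.g. zero denominator)."""


class SchemaError(InvalidInputError):
    """A file does not match its expected tabular schema."""


class EmptySelectionError(InvalidInputError):
    """Indicator selection eliminated every candidate."""


class ConsistencyError(InvalidInputError):
    """Mutually inconsistent efficiency components supplied."""


class SolverError(CareDEAError, RuntimeError):
    """The LP solver failed on a program that should be feasible."""
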