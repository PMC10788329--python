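"""Exception hierarchy.

The CLI maps these onto exit codes: :class:`ParameterError` -> 2,
:class:`DataError` (and subclasses) -> 3, :class:`NumericalError` -> 4.
"""


class PlastiqtlError(Exception):
    """Base class for all package errors."""


class ParameterError(PlastiqtlError, ValueError):
    """Invalid user-supplied parameter or configuration."""


class DataError(PlastiqtlError):
    """Input data violates a precondition (missing samples, empty panel ...)."""


class FormatError(DataError):
    """A file could not be parsed in its declared format."""


class AlignmentError(DataError):
    """Two inputs that must share an index (samples, SNPs) do not."""


class ConflictError(DataError):
    """Duplicate results for the same key (e.g. two fits for one trait/location)."""


class InsufficientDataError(DataError):
    """Too few observations to fit the requested model."""


class NumericalError(PlastiqtlError):
    """An optimizer or linear solver failed irrecoverably."""
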