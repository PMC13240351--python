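"""Exception hierarchy shared across the package."""


class OmiclockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OmiclockError):
    """Structurally invalid input (duplicate ids, empty matrix, ...)."""


class FormatError(OmiclockError):
    """Malformed file header or layout."""


class ParseError(OmiclockError):
    """A cell that should be numeric is not; names the offending row/column."""


class DomainError(OmiclockError):
    """A value outside its mathematical domain (negative TPM, age < 0, ...)."""


class ShapeError(OmiclockError):
    """Dimension mismatch between arrays that must agree."""


class DegenerateInputError(OmiclockError):
    """Input for which the operation is mathematically undefined."""


class UndefinedResultError(OmiclockError):
    """The statistic has no usable information (e.g. all pairs censored)."""
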