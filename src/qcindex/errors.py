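"""Exception hierarchy shared across the pipeline stages."""


class QCIndexError(Exception):
    """Base class for all qcindex errors."""


class SchemaError(QCIndexError):
    """A required column is missing or unmappable in an input table."""


class DataValidationError(QCIndexError):
    """A row violates a value-level invariant (negativity, bound order, ...)."""


class DuplicateKeyError(QCIndexError):
    """Two rows share the same (location, year, sex, age, measure, metric) key."""


class MissingDataError(QCIndexError):
    """An operation has nothing usable to work on (e.g. no complete ratios)."""


class InsufficientDataError(QCIndexError):
    """Fewer observations than the operation's stated minimum."""


class DegenerateInputError(QCIndexError):
    """Input is structurally unusable (constant column, non-finite matrix)."""


class OrientationError(QCIndexError):
    """The first principal component cannot be given a care-quality direction."""
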