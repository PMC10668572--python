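"""Exception hierarchy.

``UsageError`` maps to CLI exit code 1, ``DataError`` (and subclasses) to
exit code 2.
"""


class DmdSpectrumError(Exception):
    """Base class for all package errors."""


class UsageError(DmdSpectrumError):
    """The operation was invoked in a way that makes no sense."""


class DataError(DmdSpectrumError):
    """Input data violates a documented contract."""


class GeneModelError(DataError):
    """Exon reference table is structurally invalid."""


class IntervalError(DataError):
    """An exon interval is malformed or out of range."""


class NotationParseError(DataError):
    """A mutation notation string could not be parsed."""


class CohortLoadError(DataError):
    """A cohort table failed validation; lists offending rows."""


class ThresholdConfigError(DataError):
    """Copy-number threshold bins are malformed or overlapping."""


class QCError(DataError):
    """An MLPA peak table failed quality control."""
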