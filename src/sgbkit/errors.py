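"""Exception hierarchy for sgbkit.

All package errors derive from :class:`SgbkitError` so callers can catch
everything with one clause; the subclasses mirror the failure modes of the
pipeline contracts (malformed files, schema violations, incompatible
sketches, inconsistent catalogs).
"""


class SgbkitError(Exception):
    """Base class for all sgbkit errors."""


class FormatError(SgbkitError):
    """A sequence file violates its format (FASTA/FASTQ syntax)."""


class SchemaError(SgbkitError):
    """A tabular file is missing required columns."""


class ValidationError(SgbkitError):
    """A record carries values outside its contract (range, enum, duplicate id)."""


class ArgumentError(SgbkitError, ValueError):
    """An operation was called with out-of-contract arguments."""


class IncompatibleSketchError(SgbkitError):
    """Two sketches were built with different k, sketch size, or hash seed."""


class ConsistencyError(SgbkitError):
    """Cross-object invariants are violated (e.g. a MAG without an SGB)."""


class UndefinedGainError(SgbkitError):
    """Mappability gain is undefined (infinite) because the baseline is zero."""
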