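"""Exception hierarchy for data-validation failures.

All validation problems derive from :class:`TCSDataError` so callers (and the
command line) can distinguish bad data (exit code 2) from usage errors.
"""


class TCSDataError(ValueError):
    """Base class for invalid input data."""


class SchemaError(TCSDataError):
    """A table is missing a required column or uses an unknown name."""


class RowError(TCSDataError):
    """A single row violates a field-level constraint (carries the locus tag)."""


class DatasetError(TCSDataError):
    """A cross-row constraint is violated (e.g. duplicate locus tags)."""
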