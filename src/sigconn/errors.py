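"""Exception hierarchy.

Everything raised on bad user input derives from :class:`SigconnError` so
callers (and the CLI) can distinguish data problems (exit 2) from
configuration problems (exit 3, :class:`ConfigError`).
"""


class SigconnError(Exception):
    """Base class for all package errors."""


class InputError(SigconnError):
    """A required input file is missing or unreadable."""


class SchemaError(InputError):
    """An input table lacks a required column; message names the column."""


class EmptySignatureError(SigconnError):
    """Signature construction left both the up and the down side empty."""


class DuplicateEntryError(SigconnError):
    """A GRP file contains the same identifier twice."""


class AlignmentError(SigconnError):
    """Two inputs that must share a probe universe do not."""


class ValidationError(SigconnError):
    """A stored rank column is not a permutation of 1..n."""


class JoinError(SigconnError):
    """Rank matrix and instance metadata do not describe the same instances."""


class IdentifierError(SigconnError):
    """Duplicate instance identifiers in a database."""


class SizeError(SigconnError):
    """An input is too small to be meaningful (e.g. < 2 probes)."""


class CoverageError(SigconnError):
    """No query tag overlaps the database probe universe."""


class ModeError(SigconnError):
    """A planted-query was requested for a null compound."""


class ConfigError(SigconnError):
    """Invalid configuration value (thresholds, simulation parameters, ...)."""
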