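"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: schema/parse problems exit 2,
domain problems exit 3.
"""


class EpgdbkitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(EpgdbkitError):
    """Malformed input text (bad line, non-numeric count, ...)."""


class SchemaError(EpgdbkitError):
    """Structurally invalid input (missing column, duplicate key, ...)."""


class StructuralError(EpgdbkitError):
    """Inconsistent tree/table structure (unknown parent, conflicting parentage)."""


class LookupError_(EpgdbkitError):
    """A taxon or pathway identifier does not resolve."""


class AmbiguousNameError(LookupError_):
    """A taxon name matches several nodes and no disambiguation anchor decides."""


class DomainError(EpgdbkitError):
    """Arguments outside the operation's domain (empty set, zero denominator, ...)."""


class ConfigurationError(EpgdbkitError):
    """Missing or inconsistent run configuration (e.g. absent total-ORF entry)."""
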