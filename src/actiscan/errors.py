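"""Exception types shared across the pipeline."""


class ActiscanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ActiscanError):
    """An input file does not conform to the documented layout."""


class DataError(ActiscanError):
    """Input values violate a structural invariant (e.g. duplicated timestamps)."""


class DomainError(ActiscanError):
    """A value is outside the mathematical domain of an operation."""


class UsageError(ActiscanError):
    """An operation was called with an unrecognised option."""


class ConfigError(ActiscanError):
    """A simulation or run configuration is internally inconsistent."""
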