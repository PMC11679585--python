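"""Exception hierarchy shared across the package."""


class RrbsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RrbsError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(RrbsError):
    """Parsed content violates an invariant of its format or type."""


class UsageError(RrbsError):
    """An operation was invoked with an unsupported argument combination."""


class GenerationError(RrbsError):
    """The synthetic-data generator could not satisfy its constraints."""
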