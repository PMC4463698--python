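"""Exception types shared across the package."""


class PycherError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PycherError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(PycherError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(PycherError, ValueError):
    """A run configuration is invalid; raised before any stage executes."""


class StageError(PycherError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
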