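"""Exception hierarchy shared by all mresscan modules."""


class MresscanError(Exception):
    """Base class for all package errors."""


class ParseError(MresscanError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(MresscanError):
    """Inputs are individually well-formed but mutually inconsistent."""


class DomainError(MresscanError, ValueError):
    """An argument lies outside the operation's domain."""


class ConfigError(MresscanError):
    """A configuration is invalid or infeasible."""


class UsageError(MresscanError):
    """An API was called with an unknown mode or kind."""
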