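"""Exception hierarchy.

Pipeline stages map these onto distinct CLI exit codes: configuration
errors (2), data/format errors (3), anything else (1).
"""


class LoudToneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LoudToneError):
    """Invalid generator, scoring or pipeline configuration."""


class DataError(LoudToneError):
    """Input data violate an invariant (non-monotone beats, incomplete design, ...)."""


class FormatError(DataError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message, path=None, line=None):
        ctx = ""
        if path is not None:
            ctx = f"{path}:" if line is None else f"{path}:{line}:"
        super().__init__(f"{ctx} {message}" if ctx else message)
        self.path = path
        self.line = line
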