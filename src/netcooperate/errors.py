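"""Exception hierarchy for netcooperate."""


class NetCooperateError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(NetCooperateError):
    """A network file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None, source: str | None = None):
        self.line = line
        self.source = source
        prefix = ""
        if source is not None:
            prefix += f"{source}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class EmptyInputError(NetworkParseError):
    """Input contained no data rows after stripping blanks and comments."""


class SerializationError(NetCooperateError):
    """A network cannot be expressed in the requested output dialect."""


class UndefinedScoreError(NetCooperateError):
    """A cooperation score is undefined because the consumer retains no
    seed groups (e.g. the confidence threshold filtered all of them)."""


class ConsistencyError(NetCooperateError):
    """Two arguments that must describe the same network do not."""
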