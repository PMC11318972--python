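"""Exception hierarchy shared across the package."""


class ArborNetError(Exception):
    """Base class for all package-specific errors."""


class TraceParseError(ArborNetError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TraceStructureError(ArborNetError):
    """The parsed structure is inconsistent (e.g. dangling parent ids)."""


class FormatError(ArborNetError):
    """A table or JSON document violates the documented schema."""


class ValidationError(ArborNetError):
    """A value violates a domain invariant (negative area, zero hair cells...)."""


class GeometryError(ArborNetError):
    """Degenerate geometry (zero-length axis, empty boundary...)."""


class RootNotFoundError(ArborNetError):
    """No candidate arborization point could be identified."""


class EmptyGraphError(ArborNetError):
    """Graph construction was asked to run on an empty trace."""


class RegistrationError(ArborNetError):
    """A neuromast lacks the reference geometry needed for alignment."""


class ConfigError(ArborNetError):
    """A generator or pipeline configuration is infeasible."""
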