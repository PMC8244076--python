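"""Exception hierarchy shared by all cardiomesh modules."""


class CardioMeshError(Exception):
    """Base class for all cardiomesh errors."""


class InputError(CardioMeshError, ValueError):
    """Invalid or inconsistent user input (bad indices, missing fields, ...)."""


class TopologyError(CardioMeshError, ValueError):
    """Mesh connectivity violates a required invariant (non-manifold, open, ...)."""


class NumericalError(CardioMeshError, RuntimeError):
    """A numerical procedure failed (singular system, degenerate elements, ...)."""


class QualityError(CardioMeshError, RuntimeError):
    """An operation produced or met unacceptably degenerate elements."""


class ParseError(CardioMeshError, ValueError):
    """A mesh file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
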