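"""Exception hierarchy for the sbolv package."""


class SbolvError(Exception):
    """Base class for all errors raised by sbolv."""


class ExpressionError(SbolvError):
    """Malformed parametric expression (syntax, unknown function, arity)."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class EvaluationError(SbolvError):
    """Expression could not be evaluated (unbound parameter, division by zero)."""


class PathDataError(SbolvError):
    """Malformed SVG path data or parametric path template."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class GlyphValidationError(SbolvError):
    """A glyph definition violates the format invariants."""


class ColorError(SbolvError):
    """Unknown color name or malformed color literal."""


class LayoutError(SbolvError):
    """Invalid construct specification (bad index, missing glyph type...)."""


class ShorthandError(SbolvError):
    """Malformed design shorthand or interaction string."""
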