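"""Command-line shorthand for genetic designs.

A design string is a whitespace-separated list of part tokens::

    token := ['<'] code ['.' color]
    code  := 'p' | 'r' | 'c' | 't' | 'x'

where ``p`` = promoter, ``r`` = RBS, ``c`` = CDS, ``t`` = terminator,
``x`` = recombination site; a ``<`` prefix reverses the part's direction.
Colors are CSS names or hex triplets; an ``l_`` prefix denotes a lighter
version of the named color (blended halfway toward white per RGB channel).
The color is applied as the fill of the glyph's primary (first) path — and
to its stroke as well when that path has no fill, so stroke-only glyphs
still show the color.

An interaction string has four ``//``-separated fields: start part index,
end part index, type code (``in`` = inhibition, ``co`` = control) and
color, e.g. ``0//2//in//red``.
"""

from __future__ import annotations

from dataclasses import dataclass

from matplotlib.colors import CSS4_COLORS

from .errors import ColorError, ShorthandError
from .layout import Interaction, Part
from .render import normalize_color

__all__ = [
    "DesignToken",
    "CODE_TO_TYPE",
    "INTERACTION_CODES",
    "parse_design_tokens",
    "parse_design_string",
    "serialize_design_tokens",
    "parse_interaction_string",
    "lighten_color",
    "resolve_color_token",
]

CODE_TO_TYPE = {
    "p": "Promoter",
    "r": "RBS",
    "c": "CDS",
    "t": "Terminator",
    "x": "RecombinationSite",
}

INTERACTION_CODES = {"in": "inhibition", "co": "control"}

#: path that receives the token's color, per glyph type (first visible path)
PRIMARY_PATH = {
    "Promoter": "stem",
    "RBS": "body",
    "CDS": "body",
    "Terminator": "stem",
    "RecombinationSite": "body",
}

#: default fill of the primary path; None means the glyph is stroke-only
_PRIMARY_HAS_FILL = {"Promoter": False, "RBS": True, "CDS": True,
                     "Terminator": False, "RecombinationSite": True}


@dataclass(frozen=True)
class DesignToken:
    """One parsed token of a design string."""

    code: str
    reverse: bool = False
    color: str | None = None  # raw token, possibly with an l_ prefix

    @property
    def glyph_type(self) -> str:
        return CODE_TO_TYPE[self.code]


def lighten_color(name: str) -> str:
    """Resolve an ``l_``-prefixed color: base color blended 50% toward white.

    Returns a hex triplet; unknown base colors are an error.
    """
    if not name.startswith("l_"):
        raise ColorError(f"{name!r} has no 'l_' prefix")
    base = name[2:].lower()
    try:
        hex_color = CSS4_COLORS[base]
    except KeyError:
        raise ColorError(f"unknown color {base!r}") from None
    channels = [int(hex_color[i : i + 2], 16) for i in (1, 3, 5)]
    lightened = [int(c + 0.5 * (255 - c) + 0.5) for c in channels]
    return "#{:02x}{:02x}{:02x}".format(*lightened)


def resolve_color_token(token: str) -> str:
    """Resolve a shorthand color token (name, hex, or ``l_`` form) to hex."""
    if token.startswith("l_"):
        return lighten_color(token)
    return normalize_color(token)


def parse_design_tokens(s: str) -> list[DesignToken]:
    """Tokenize a design string; errors carry the 1-based token position."""
    if not s or not s.strip():
        raise ShorthandError("empty design string")
    tokens: list[DesignToken] = []
    for pos, raw in enumerate(s.split(), start=1):
        text = raw
        reverse = False
        if text.startswith("<"):
            reverse = True
            text = text[1:]
        color = None
        if "." in text:
            text, _, color = text.partition(".")
            if not color:
                raise ShorthandError(f"token {pos} ({raw!r}): empty color")
        if text not in CODE_TO_TYPE:
            raise ShorthandError(
                f"token {pos} ({raw!r}): unknown part code {text!r}; "
                f"valid codes: {', '.join(CODE_TO_TYPE)}"
            )
        if color is not None:
            try:
                resolve_color_token(color)
            except ColorError as exc:
                raise ShorthandError(f"token {pos} ({raw!r}): {exc}") from exc
        tokens.append(DesignToken(code=text, reverse=reverse, color=color))
    return tokens


def _token_to_part(token: DesignToken) -> Part:
    user_style: dict[str, dict] = {}
    if token.color is not None:
        color = resolve_color_token(token.color)
        primary = PRIMARY_PATH[token.glyph_type]
        style: dict = {"fill": color}
        if not _PRIMARY_HAS_FILL[token.glyph_type]:
            style["stroke"] = color
        user_style[primary] = style
    return Part(
        glyph_type=token.glyph_type,
        orientation="reverse" if token.reverse else "forward",
        user_style=user_style,
    )


def parse_design_string(s: str) -> list[Part]:
    """Parse a design string into construct parts."""
    return [_token_to_part(t) for t in parse_design_tokens(s)]


def serialize_design_tokens(tokens: list[DesignToken]) -> str:
    """Inverse of :func:`parse_design_tokens` (canonical spacing)."""
    out = []
    for t in tokens:
        text = ("<" if t.reverse else "") + t.code
        if t.color is not None:
            text += "." + t.color
        out.append(text)
    return " ".join(out)


def parse_interaction_string(s: str) -> Interaction:
    """Parse ``start//end//type//color`` into an :class:`Interaction`."""
    if not s or not s.strip():
        raise ShorthandError("empty interaction string")
    fields = s.strip().split("//")
    if len(fields) != 4:
        raise ShorthandError(
            f"interaction {s!r}: expected 4 '//'-separated fields "
            f"(start//end//type//color), got {len(fields)}"
        )
    raw_from, raw_to, code, color = fields
    try:
        from_index, to_index = int(raw_from), int(raw_to)
    except ValueError:
        raise ShorthandError(
            f"interaction {s!r}: indices must be integers"
        ) from None
    if code not in INTERACTION_CODES:
        raise ShorthandError(
            f"interaction {s!r}: unknown type code {code!r}; "
            f"valid: {', '.join(INTERACTION_CODES)}"
        )
    try:
        resolved = resolve_color_token(color)
    except ColorError as exc:
        raise ShorthandError(f"interaction {s!r}: {exc}") from exc
    return Interaction(
        from_index=from_index,
        to_index=to_index,
        kind=INTERACTION_CODES[code],
        color=resolved,
    )
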