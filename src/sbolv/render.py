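"""Single-glyph rendering onto an abstract canvas.

Drawing a glyph means: resolve parameters (defaults overlaid by user
values), evaluate every parametric path template, orient the geometry
(reverse-strand parts are rotated 180 degrees about the midpoint of their
own baseline, so the baseline extent is preserved), translate so the
baseline start sits on the requested anchor, and paint each path with its
default style overlaid by any per-path user style.

The return value is the composition contract: the bounds of the painted
geometry plus the start and end points of the baseline, which is where the
next glyph in a design goes.

The :class:`Canvas` contract is a painter's model (draw order preserved);
:class:`SVGCanvas` is the reference backend and finalizes to an SVG 1.1
document whose view box covers everything drawn plus a margin.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from matplotlib.colors import CSS4_COLORS

from .errors import ColorError, GlyphValidationError, LayoutError
from .geometry import (
    Bounds,
    PathCommand,
    Transform2D,
    apply_transform,
    path_bounds,
    serialize_path_data,
)
from .model import SVG_NS, GlyphDefinition, GlyphLibrary, Style

__all__ = [
    "RenderResult",
    "Canvas",
    "SVGCanvas",
    "GlyphRenderer",
    "resolve_parameters",
    "normalize_color",
]

_HEX_RE = re.compile(r"#(?:[0-9a-fA-F]{3}|[0-9a-fA-F]{6})$")


def normalize_color(color: str) -> str:
    """Validate a color given as a CSS named color or hex triplet.

    Returns the lowercase hex form.  Raises :class:`ColorError` for
    anything else.
    """
    if _HEX_RE.match(color):
        if len(color) == 4:
            color = "#" + "".join(c * 2 for c in color[1:])
        return color.lower()
    try:
        return CSS4_COLORS[color.lower()].lower()
    except KeyError:
        raise ColorError(f"unknown color {color!r}") from None


@dataclass(frozen=True)
class RenderResult:
    """Composition contract returned after drawing one glyph."""

    bounds: Bounds
    baseline_start: tuple[float, float]
    baseline_end: tuple[float, float]

    @property
    def baseline_span(self) -> float:
        return self.baseline_end[0] - self.baseline_start[0]


class Canvas:
    """Abstract drawing surface (painter's model; y grows downward)."""

    def draw_path(
        self, commands: list[PathCommand], style: Style, element_id: str
    ) -> None:
        raise NotImplementedError

    def draw_text(self, text: str, x: float, y: float, font_size: float = 7.0) -> None:
        raise NotImplementedError

    def finalize(self) -> str:
        raise NotImplementedError


@dataclass
class SVGCanvas(Canvas):
    """Canvas backend emitting an SVG 1.1 document."""

    margin: float = 5.0
    _elements: list[tuple] = field(default_factory=list)
    _bounds: Bounds | None = field(default=None)

    @property
    def path_count(self) -> int:
        return sum(1 for kind, *_ in self._elements if kind == "path")

    def draw_path(self, commands, style, element_id):
        checked = dict(
            fill=style.fill and normalize_color(style.fill),
            stroke=style.stroke and normalize_color(style.stroke),
            stroke_width=style.stroke_width,
            opacity=style.opacity,
        )
        self._elements.append(
            ("path", serialize_path_data(commands), Style(**checked), element_id)
        )
        self._grow(path_bounds(commands))

    def draw_text(self, text, x, y, font_size=7.0):
        self._elements.append(("text", text, x, y, font_size))
        self._grow(Bounds(x, y - font_size, x, y))

    def _grow(self, b: Bounds) -> None:
        self._bounds = b if self._bounds is None else self._bounds.union(b)

    def view_box(self) -> Bounds:
        if self._bounds is None:
            return Bounds(0, 0, 10, 10)
        return self._bounds.expanded(self.margin)

    def finalize(self) -> str:
        box = self.view_box()
        root = ET.Element(
            f"{{{SVG_NS}}}svg",
            {
                "viewBox": f"{box.xmin:g} {box.ymin:g} {box.width:g} {box.height:g}",
                "width": f"{box.width:g}",
                "height": f"{box.height:g}",
            },
        )
        for element in self._elements:
            if element[0] == "path":
                _, d, style, element_id = element
                el = ET.SubElement(root, f"{{{SVG_NS}}}path", {"id": element_id, "d": d})
                el.set("style", style.to_css())
            else:
                _, text, x, y, font_size = element
                el = ET.SubElement(
                    root,
                    f"{{{SVG_NS}}}text",
                    {
                        "x": f"{x:g}",
                        "y": f"{y:g}",
                        "style": f"font-size:{font_size:g}px;text-anchor:middle",
                    },
                )
                el.text = text
        return ET.tostring(root, encoding="unicode", xml_declaration=True)


def resolve_parameters(
    glyph: GlyphDefinition, user: dict[str, float] | None
) -> dict[str, float]:
    """Overlay *user* values onto the glyph defaults.

    The result binds exactly the keys of the defaults; a user key the glyph
    does not declare is an error naming the key and the valid parameters.
    """
    resolved = dict(glyph.defaults)
    for key, value in (user or {}).items():
        if key not in resolved:
            raise GlyphValidationError(
                f"glyph {glyph.glyph_type!r} has no parameter {key!r}; "
                f"valid parameters: {', '.join(sorted(resolved)) or '(none)'}"
            )
        value = float(value)
        if value != value or value in (float("inf"), float("-inf")):
            raise GlyphValidationError(f"value for {key!r} is not finite")
        resolved[key] = value
    return resolved


@dataclass(frozen=True)
class _Placed:
    """Concrete, transformed geometry of one glyph instance."""

    paths: list[tuple[str, list[PathCommand], Style]]
    result: RenderResult


class GlyphRenderer:
    """Draws glyphs from a library onto a canvas.

    One renderer is typically created per application and reused for every
    glyph in a diagram; it assigns each drawn glyph a monotonically
    increasing instance index used in the emitted SVG path ids
    (``"<glyph_type>.<path_name>.<instance_index>"``).
    """

    def __init__(self, library: GlyphLibrary):
        self.library = library
        self._instances = 0

    def glyph_geometry(
        self,
        glyph_type: str,
        anchor: tuple[float, float] = (0.0, 0.0),
        orientation: str = "forward",
        user_parameters: dict[str, float] | None = None,
        user_style: dict[str, dict] | None = None,
    ) -> _Placed:
        """Compute the placed geometry and contract without painting."""
        if orientation not in ("forward", "reverse"):
            raise LayoutError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
        try:
            glyph = self.library[glyph_type]
        except KeyError as exc:
            raise LayoutError(str(exc)) from None
        params = resolve_parameters(glyph, user_parameters)
        styles = self._resolve_styles(glyph, user_style)

        (bx0, by0), (bx1, _) = glyph.baseline_points(params)
        transform = Transform2D.translation(anchor[0] - bx0, anchor[1] - by0)
        if orientation == "reverse":
            midpoint = ((bx0 + bx1) / 2, by0)
            transform = transform @ Transform2D.point_reflection(*midpoint)

        placed_paths = []
        bounds: Bounds | None = None
        for p in glyph.paths:
            commands = apply_transform(p.commands_at(params), transform)
            placed_paths.append((p.name, commands, styles[p.name]))
            b = path_bounds(commands)
            bounds = b if bounds is None else bounds.union(b)
        span = bx1 - bx0
        result = RenderResult(
            bounds=bounds if bounds is not None else Bounds(*anchor, *anchor),
            baseline_start=anchor,
            baseline_end=(anchor[0] + span, anchor[1]),
        )
        return _Placed(placed_paths, result)

    def draw_glyph(
        self,
        glyph_type: str,
        anchor: tuple[float, float] = (0.0, 0.0),
        orientation: str = "forward",
        user_parameters: dict[str, float] | None = None,
        user_style: dict[str, dict] | None = None,
        canvas: Canvas | None = None,
    ) -> RenderResult:
        """Draw one glyph and return the composition contract.

        The anchor is the start point of the glyph's baseline.  Marker
        paths (baseline, bounding box) are never painted.
        """
        placed = self.glyph_geometry(
            glyph_type, anchor, orientation, user_parameters, user_style
        )
        if canvas is not None:
            index = self._instances
            self._instances += 1
            for name, commands, style in placed.paths:
                canvas.draw_path(commands, style, f"{glyph_type}.{name}.{index}")
        return placed.result

    @staticmethod
    def _resolve_styles(
        glyph: GlyphDefinition, user_style: dict[str, dict] | None
    ) -> dict[str, Style]:
        styles = {p.name: p.style for p in glyph.paths}
        for name, overrides in (user_style or {}).items():
            if name not in styles:
                raise GlyphValidationError(
                    f"glyph {glyph.glyph_type!r} has no path {name!r}; "
                    f"paths: {', '.join(styles)}"
                )
            styles[name] = styles[name].merged(**overrides)
        return styles
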