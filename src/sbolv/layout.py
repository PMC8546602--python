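"""Whole-construct layout: baseline chaining, interaction arcs, line wrapping.

A construct is an ordered list of oriented parts on a shared DNA baseline
plus regulatory interactions between parts.  Layout is pure x-chaining:
part 0 is anchored at the construct start and each subsequent part starts
``part_spacing`` units after the previous part's baseline end (reverse
orientation preserves baseline extent, so it never shifts the chain).

Interaction arcs run from above the source part to above the target part.
Arcs over overlapping part spans are stacked deterministically: processed
in input order, each arc clears the tallest glyph under it by
``base_clearance_factor`` times that height and rises one ``level_step``
per previously routed arc whose span overlaps its own.  The terminal
decoration encodes the interaction kind: inhibition ends in a bar
perpendicular to the (vertical) approach, control in an open diamond,
stimulation in an open arrowhead.

Long designs wrap greedily across lines: a part opens a new row when it
would overflow ``max_line_width``, unless it is the row's first part
(oversized parts get a row of their own).  Rows are stacked
``line_spacing`` units apart, each with its own continuous backbone line.
An interaction whose endpoints fall on different rows is drawn in the
source part's row and truncated at the row edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LayoutError
from .geometry import Bounds, PathCommand, path_bounds
from .model import GlyphLibrary, Style
from .render import Canvas, GlyphRenderer, RenderResult, normalize_color

__all__ = [
    "Part",
    "Interaction",
    "ConstructSpec",
    "PlacedPart",
    "Arc",
    "layout_parts",
    "wrap_lines",
    "route_interaction",
    "render_construct",
]

INTERACTION_KINDS = ("inhibition", "control", "stimulation")

#: size of the terminal decoration (bar half-width, diamond/arrow radius)
_DECORATION_SIZE = 3.0
#: gap between a part's top and the arc's vertical riser / decoration
_APPROACH_GAP = 2.0


@dataclass(frozen=True)
class Part:
    """One oriented part of a construct."""

    glyph_type: str
    orientation: str = "forward"
    user_parameters: dict[str, float] = field(default_factory=dict)
    user_style: dict[str, dict] = field(default_factory=dict)
    label: str | None = None
    width_hint: float | None = None

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise LayoutError(f"bad orientation {self.orientation!r}")
        if self.width_hint is not None and self.width_hint <= 0:
            raise LayoutError("width_hint must be positive")

    def effective_parameters(self, lib: GlyphLibrary) -> dict[str, float]:
        params = dict(self.user_parameters)
        if self.width_hint is not None:
            if "width" not in lib[self.glyph_type].defaults:
                raise LayoutError(
                    f"glyph {self.glyph_type!r} has no 'width' parameter; "
                    "width_hint is not applicable"
                )
            params["width"] = self.width_hint
        return params


@dataclass(frozen=True)
class Interaction:
    """A regulatory arc between two part indices (0-based)."""

    from_index: int
    to_index: int
    kind: str
    color: str = "black"

    def __post_init__(self):
        if self.kind not in INTERACTION_KINDS:
            raise LayoutError(
                f"unknown interaction kind {self.kind!r}; "
                f"valid: {', '.join(INTERACTION_KINDS)}"
            )
        if self.from_index == self.to_index:
            raise LayoutError("interaction endpoints must differ")
        if min(self.from_index, self.to_index) < 0:
            raise LayoutError("interaction indices must be nonnegative")
        normalize_color(self.color)

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.from_index, self.to_index), max(self.from_index, self.to_index))


@dataclass(frozen=True)
class ConstructSpec:
    """A renderable design: parts, interactions and layout parameters."""

    parts: tuple[Part, ...]
    interactions: tuple[Interaction, ...] = ()
    part_spacing: float = 4.0
    start: tuple[float, float] = (0.0, 0.0)
    max_line_width: float | None = None
    line_spacing: float = 40.0
    base_clearance_factor: float = 1.2
    level_step: float = 6.0

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        if self.part_spacing < 0 or self.line_spacing < 0:
            raise LayoutError("spacings must be nonnegative")
        if self.max_line_width is not None and self.max_line_width <= 0:
            raise LayoutError("max_line_width must be positive")
        for i in self.interactions:
            if max(i.from_index, i.to_index) >= len(self.parts):
                raise LayoutError(
                    f"interaction index {max(i.from_index, i.to_index)} out of "
                    f"range for {len(self.parts)} part(s)"
                )


@dataclass(frozen=True)
class PlacedPart:
    part: Part
    index: int
    row: int
    anchor: tuple[float, float]
    result: RenderResult


@dataclass(frozen=True)
class Arc:
    """Routed interaction geometry ready to paint."""

    interaction: Interaction
    index: int
    level: int
    spine: list[PathCommand]
    decoration: list[PathCommand] | None
    decoration_name: str | None


def _measure(renderer: GlyphRenderer, part: Part, anchor, row=0, index=0) -> PlacedPart:
    placed = renderer.glyph_geometry(
        part.glyph_type,
        anchor=anchor,
        orientation=part.orientation,
        user_parameters=part.effective_parameters(renderer.library),
        user_style=part.user_style,
    )
    return PlacedPart(part, index, row, anchor, placed.result)


def layout_parts(spec: ConstructSpec, lib: GlyphLibrary) -> list[PlacedPart]:
    """Chain all parts along one baseline starting at ``spec.start``.

    No wrapping is applied here; see :func:`wrap_lines`.
    """
    renderer = GlyphRenderer(lib)
    placed: list[PlacedPart] = []
    x, y = spec.start
    for i, part in enumerate(spec.parts):
        pp = _measure(renderer, part, (x, y), row=0, index=i)
        placed.append(pp)
        x = pp.result.baseline_end[0] + spec.part_spacing
    return placed


def _baseline_span(renderer: GlyphRenderer, part: Part) -> float:
    return _measure(renderer, part, (0.0, 0.0)).result.baseline_span


def wrap_lines(spec: ConstructSpec, lib: GlyphLibrary) -> list[list[Part]]:
    """Greedy left-to-right row fill honoring ``max_line_width``.

    Part order is preserved and every part appears in exactly one row; a
    part wider than the limit occupies a row by itself.
    """
    if spec.max_line_width is None:
        return [list(spec.parts)]
    renderer = GlyphRenderer(lib)
    rows: list[list[Part]] = []
    current: list[Part] = []
    x = 0.0
    for part in spec.parts:
        span = _baseline_span(renderer, part)
        end = (x + spec.part_spacing if current else 0.0) + span
        if current and end > spec.max_line_width:
            rows.append(current)
            current = [part]
            x = span
        else:
            current.append(part)
            x = end
    if current:
        rows.append(current)
    return rows


def route_interaction(
    interaction: Interaction,
    layout: list[PlacedPart],
    spec: ConstructSpec,
    routed: tuple[Interaction, ...] = (),
    index: int = 0,
) -> Arc:
    """Route one interaction arc over an already computed layout.

    *routed* are the previously processed interactions (input order); the
    arc's stacking level is the number of them whose part-index span
    overlaps this interaction's span.
    """
    n = len(layout)
    if not (0 <= interaction.from_index < n and 0 <= interaction.to_index < n):
        raise LayoutError(
            f"interaction index out of range for {n} placed part(s)"
        )
    lo, hi = interaction.span
    level = sum(1 for other in routed if _spans_overlap(other.span, (lo, hi)))

    src = layout[interaction.from_index]
    dst = layout[interaction.to_index]
    baseline_y = src.anchor[1]
    span_height = max(
        baseline_y - layout[i].result.bounds.ymin for i in range(lo, hi + 1)
    )
    apex_y = baseline_y - (
        spec.base_clearance_factor * span_height + level * spec.level_step
    )

    x_src = src.result.bounds.center[0]
    x_dst = dst.result.bounds.center[0]
    y_src = src.result.bounds.ymin - _APPROACH_GAP

    same_row = dst.row == src.row
    if same_row:
        y_dst_stop = dst.result.bounds.ymin - _APPROACH_GAP - _DECORATION_SIZE
        spine = [
            PathCommand("M", (x_src, y_src)),
            PathCommand("L", (x_src, apex_y)),
            PathCommand("L", (x_dst, apex_y)),
            PathCommand("L", (x_dst, y_dst_stop)),
        ]
        decoration, decoration_name = _decorate(
            interaction.kind, x_dst, y_dst_stop
        )
    else:
        # target on another row: truncate at this row's edge, no decoration
        row_edge = max(p.result.baseline_end[0] for p in layout if p.row == src.row)
        spine = [
            PathCommand("M", (x_src, y_src)),
            PathCommand("L", (x_src, apex_y)),
            PathCommand("L", (row_edge, apex_y)),
        ]
        decoration, decoration_name = None, None
    return Arc(interaction, index, level, spine, decoration, decoration_name)


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


def _decorate(kind: str, x: float, y: float):
    """Terminal decoration just below the arc's descent stop (x, y)."""
    s = _DECORATION_SIZE
    if kind == "inhibition":
        # bar perpendicular to the vertical approach
        return [PathCommand("M", (x - s, y)), PathCommand("L", (x + s, y))], "bar"
    if kind == "control":
        return (
            [
                PathCommand("M", (x, y)),
                PathCommand("L", (x + s, y + s)),
                PathCommand("L", (x, y + 2 * s)),
                PathCommand("L", (x - s, y + s)),
                PathCommand("Z"),
            ],
            "diamond",
        )
    # stimulation: open arrowhead pointing down toward the target
    return (
        [
            PathCommand("M", (x - s, y)),
            PathCommand("L", (x, y + s)),
            PathCommand("L", (x + s, y)),
        ],
        "arrow",
    )


def render_construct(
    spec: ConstructSpec, lib: GlyphLibrary, canvas: Canvas
) -> Bounds:
    """Render the whole construct (backbones, parts, arcs) in one call.

    Returns the union bounds of everything drawn.
    """
    renderer = GlyphRenderer(lib)
    rows = wrap_lines(spec, lib)

    placed: list[PlacedPart] = []
    index = 0
    x0, y0 = spec.start
    for row_i, row in enumerate(rows):
        x = x0
        y = y0 + row_i * spec.line_spacing
        for part in row:
            pp = _measure(renderer, part, (x, y), row=row_i, index=index)
            placed.append(pp)
            x = pp.result.baseline_end[0] + spec.part_spacing
            index += 1

    bounds: Bounds | None = None

    def grow(b: Bounds):
        nonlocal bounds
        bounds = b if bounds is None else bounds.union(b)

    # backbone beneath the parts of each row
    row_parts: dict[int, list[PlacedPart]] = {}
    for pp in placed:
        row_parts.setdefault(pp.row, []).append(pp)
    backbone_style = Style(fill=None, stroke="black", stroke_width=1.5)
    for row_i, pps in sorted(row_parts.items()):
        xs0 = pps[0].result.baseline_start
        xs1 = pps[-1].result.baseline_end
        commands = [PathCommand("M", xs0), PathCommand("L", xs1)]
        canvas.draw_path(commands, backbone_style, f"backbone.{row_i}")
        grow(path_bounds(commands))

    # parts (re-drawn through the renderer so instance ids are assigned)
    for pp in placed:
        result = renderer.draw_glyph(
            pp.part.glyph_type,
            anchor=pp.anchor,
            orientation=pp.part.orientation,
            user_parameters=pp.part.effective_parameters(lib),
            user_style=pp.part.user_style,
            canvas=canvas,
        )
        grow(result.bounds)
        if pp.part.label:
            canvas.draw_text(
                pp.part.label,
                (result.baseline_start[0] + result.baseline_end[0]) / 2,
                pp.anchor[1] + 10.0,
            )
            grow(Bounds(result.baseline_start[0], pp.anchor[1], result.baseline_end[0], pp.anchor[1] + 10.0))

    # interaction arcs on top
    routed: list[Interaction] = []
    for arc_i, interaction in enumerate(spec.interactions):
        arc = route_interaction(interaction, placed, spec, tuple(routed), arc_i)
        routed.append(interaction)
        color = interaction.color
        line_style = Style(fill=None, stroke=color, stroke_width=1.0)
        base_id = f"interaction.{interaction.kind}.{arc.index}"
        canvas.draw_path(arc.spine, line_style, base_id)
        grow(path_bounds(arc.spine))
        if arc.decoration is not None:
            deco_style = Style(
                fill=None if arc.decoration_name != "diamond" else "white",
                stroke=color,
                stroke_width=1.0,
            )
            canvas.draw_path(
                arc.decoration, deco_style, f"{base_id}.{arc.decoration_name}"
            )
            grow(path_bounds(arc.decoration))

    if bounds is None:
        return Bounds(x0, y0, x0, y0)
    return bounds
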