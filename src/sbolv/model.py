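"""Reading, writing and validating parametric SVG (pSVG) glyph definitions.

A pSVG file is an ordinary SVG document extended with attributes in a
``parametric`` XML namespace, so any standard SVG consumer can still render
the default shape:

* each ``path`` element carries the baked default shape in its standard
  ``d`` attribute and, optionally, a ``parametric:d`` template in which
  coordinates are ``{expression}`` formulas over named parameters;
* the root ``svg`` element carries the parameter defaults as a
  ``parametric:defaults`` attribute encoded as semicolon-separated
  ``name=value`` pairs, and the SBOL Visual term for the glyph in a
  ``glyphtype`` attribute;
* two specially named paths, ``id="baseline"`` and ``id="bounding-box"``,
  encode the composition contract: the horizontal DNA baseline whose start
  anchors the glyph and whose end locates the next glyph, and the rectangle
  the glyph occupies.  They are never painted when the glyph is rendered.

Validation enforces the format invariants: parameter closure (defaults bind
every referenced parameter), the default-evaluation identity (the template
evaluated at the defaults reproduces the baked ``d`` coordinates), a
horizontal baseline spanning the bounding box, and geometry contained in
the bounding box.
"""

from __future__ import annotations

import io
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import GlyphValidationError, PathDataError
from .geometry import (
    Bounds,
    PathCommand,
    evaluate_template,
    parse_path_data,
    path_bounds,
    serialize_path_data,
    template_parameters,
)

__all__ = [
    "PARAMETRIC_NS",
    "SVG_NS",
    "Style",
    "ParametricPath",
    "GlyphDefinition",
    "GlyphLibrary",
    "read_glyph",
    "write_glyph",
    "load_library",
]

SVG_NS = "http://www.w3.org/2000/svg"
PARAMETRIC_NS = "urn:sbolv:parametric"

ET.register_namespace("", SVG_NS)
ET.register_namespace("parametric", PARAMETRIC_NS)

#: reserved path ids that carry composition metadata, never painted
MARKER_IDS = ("baseline", "bounding-box")

DEFAULT_IDENTITY_TOL = 1e-9
BBOX_CONTAINMENT_TOL = 1e-6


@dataclass(frozen=True)
class Style:
    """Inline path style: fill/stroke paint, stroke width, opacity.

    ``None`` paint means "none" (not painted).
    """

    fill: str | None = None
    stroke: str | None = "black"
    stroke_width: float = 1.0
    opacity: float = 1.0

    def to_css(self) -> str:
        parts = [
            f"fill:{self.fill if self.fill is not None else 'none'}",
            f"stroke:{self.stroke if self.stroke is not None else 'none'}",
            f"stroke-width:{self.stroke_width:g}",
        ]
        if self.opacity != 1.0:
            parts.append(f"opacity:{self.opacity:g}")
        return ";".join(parts)

    @classmethod
    def from_css(cls, text: str) -> "Style":
        values: dict[str, str] = {}
        for item in text.split(";"):
            item = item.strip()
            if not item:
                continue
            if ":" not in item:
                raise GlyphValidationError(f"malformed style declaration {item!r}")
            key, value = item.split(":", 1)
            values[key.strip()] = value.strip()
        fill = values.get("fill")
        stroke = values.get("stroke", "black")
        return cls(
            fill=None if fill in (None, "none") else fill,
            stroke=None if stroke == "none" else stroke,
            stroke_width=float(values.get("stroke-width", 1.0)),
            opacity=float(values.get("opacity", 1.0)),
        )

    def merged(self, **overrides) -> "Style":
        known = {"fill", "stroke", "stroke_width", "opacity"}
        bad = set(overrides) - known
        if bad:
            raise GlyphValidationError(
                f"unknown style option(s) {sorted(bad)}; valid: {sorted(known)}"
            )
        return replace(self, **overrides)


@dataclass(frozen=True)
class ParametricPath:
    """A named path of a glyph: baked shape plus optional parametric template."""

    name: str
    static_d: str
    parametric_d: str | None = None
    style: Style = Style()

    def parameters(self) -> set[str]:
        if self.parametric_d is None:
            return set()
        return template_parameters(self.parametric_d)

    def commands_at(self, binding: dict[str, float]) -> list[PathCommand]:
        """Concrete commands at *binding* (falls back to the baked shape)."""
        if self.parametric_d is None:
            return parse_path_data(self.static_d)
        return parse_path_data(evaluate_template(self.parametric_d, binding))


@dataclass
class GlyphDefinition:
    """One SBOL Visual glyph: named paths, defaults, baseline, bounding box."""

    glyph_type: str
    paths: list[ParametricPath]
    defaults: dict[str, float]
    baseline: ParametricPath
    bounding_box: ParametricPath

    def path(self, name: str) -> ParametricPath:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(name)

    def path_names(self) -> list[str]:
        return [p.name for p in self.paths]

    def baseline_points(
        self, binding: dict[str, float] | None = None
    ) -> tuple[tuple[float, float], tuple[float, float]]:
        """(start, end) of the baseline segment at *binding* (defaults if None)."""
        cmds = self.baseline.commands_at(binding or self.defaults)
        return cmds[0].end, cmds[-1].end

    def box_bounds(self, binding: dict[str, float] | None = None) -> Bounds:
        return path_bounds(self.bounding_box.commands_at(binding or self.defaults))

    def parameters(self) -> set[str]:
        names: set[str] = set()
        for p in [*self.paths, self.baseline, self.bounding_box]:
            names |= p.parameters()
        return names

    def validate(self) -> None:
        """Raise :class:`GlyphValidationError` on any invariant violation."""
        if not self.glyph_type:
            raise GlyphValidationError("glyph_type must be nonempty")
        seen: set[str] = set()
        for p in self.paths:
            if not p.name:
                raise GlyphValidationError("path name must be nonempty")
            if p.name in seen:
                raise GlyphValidationError(f"duplicate path name {p.name!r}")
            if p.name in MARKER_IDS:
                raise GlyphValidationError(
                    f"path name {p.name!r} is reserved for composition markers"
                )
            seen.add(p.name)
        for name, value in self.defaults.items():
            if value != value or value in (float("inf"), float("-inf")):
                raise GlyphValidationError(f"default for {name!r} is not finite")
        for p in self._all_paths():
            self._validate_path(p)
        self._validate_composition()

    def _all_paths(self) -> list[ParametricPath]:
        return [*self.paths, self.baseline, self.bounding_box]

    def _validate_path(self, p: ParametricPath) -> None:
        try:
            static_cmds = parse_path_data(p.static_d)
        except PathDataError as exc:
            raise GlyphValidationError(
                f"path {p.name!r}: invalid static path data: {exc}"
            ) from exc
        if p.parametric_d is None:
            return
        missing = sorted(p.parameters() - set(self.defaults))
        if missing:
            raise GlyphValidationError(
                f"path {p.name!r} references parameter(s) "
                f"{', '.join(repr(m) for m in missing)} absent from defaults"
            )
        evaluated = evaluate_template(p.parametric_d, self.defaults)
        eval_cmds = parse_path_data(evaluated)
        dev = _max_deviation(static_cmds, eval_cmds)
        if dev is None or dev > DEFAULT_IDENTITY_TOL:
            shown = "structure differs" if dev is None else f"max deviation {dev:g}"
            raise GlyphValidationError(
                f"path {p.name!r}: parametric template at defaults does not "
                f"reproduce the static shape ({shown})"
            )

    def _validate_composition(self) -> None:
        (x0, y0), (x1, y1) = self.baseline_points()
        if abs(y0 - y1) > DEFAULT_IDENTITY_TOL:
            raise GlyphValidationError("baseline is not horizontal")
        box = self.box_bounds()
        if box.width <= 0:
            raise GlyphValidationError("bounding box must have positive width")
        tol = BBOX_CONTAINMENT_TOL
        if abs(min(x0, x1) - box.xmin) > tol or abs(max(x0, x1) - box.xmax) > tol:
            raise GlyphValidationError(
                "baseline does not span the bounding box horizontally"
            )
        for p in self.paths:
            b = path_bounds(p.commands_at(self.defaults))
            if not box.contains(b, tol):
                raise GlyphValidationError(
                    f"path {p.name!r} geometry at defaults exceeds the bounding box"
                )


def _max_deviation(
    a: list[PathCommand], b: list[PathCommand]
) -> float | None:
    """Max coordinate deviation between equally structured command lists.

    Returns None when opcodes or arities differ.
    """
    if len(a) != len(b):
        return None
    dev = 0.0
    for ca, cb in zip(a, b):
        if ca.op != cb.op or len(ca.args) != len(cb.args):
            return None
        for va, vb in zip(ca.args, cb.args):
            dev = max(dev, abs(va - vb))
    return dev


@dataclass
class GlyphLibrary:
    """Mapping of SBOL Visual glyph type to its definition."""

    glyphs: dict[str, GlyphDefinition] = field(default_factory=dict)

    def __contains__(self, glyph_type: str) -> bool:
        return glyph_type in self.glyphs

    def __getitem__(self, glyph_type: str) -> GlyphDefinition:
        try:
            return self.glyphs[glyph_type]
        except KeyError:
            raise KeyError(
                f"unknown glyph type {glyph_type!r}; available: "
                f"{', '.join(sorted(self.glyphs))}"
            ) from None

    def __len__(self) -> int:
        return len(self.glyphs)

    def __iter__(self):
        return iter(self.glyphs.values())

    def types(self) -> list[str]:
        return list(self.glyphs)

    def add(self, glyph: GlyphDefinition) -> None:
        if glyph.glyph_type in self.glyphs:
            raise GlyphValidationError(
                f"duplicate glyph type {glyph.glyph_type!r}"
            )
        self.glyphs[glyph.glyph_type] = glyph


# ---------------------------------------------------------------------------
# reading

def _parse_defaults(text: str) -> dict[str, float]:
    defaults: dict[str, float] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GlyphValidationError(
                f"malformed defaults entry {item!r} (expected name=value)"
            )
        name, value = item.split("=", 1)
        name = name.strip()
        if name in defaults:
            raise GlyphValidationError(f"duplicate default for parameter {name!r}")
        try:
            defaults[name] = float(value)
        except ValueError:
            raise GlyphValidationError(
                f"default for {name!r} is not a number: {value!r}"
            ) from None
    return defaults


def _serialize_defaults(defaults: dict[str, float]) -> str:
    from .geometry import format_number

    return ";".join(f"{k}={format_number(v)}" for k, v in defaults.items())


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_glyph(source, validate: bool = True) -> GlyphDefinition:
    """Read a pSVG glyph from a file path, file object or XML string."""
    if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("<"):
        text = Path(source).read_text()
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise GlyphValidationError(f"not well-formed XML: {exc}") from exc
    if _local(root.tag) != "svg":
        raise GlyphValidationError(f"root element is {_local(root.tag)!r}, not 'svg'")

    glyph_type = root.get(f"{{{PARAMETRIC_NS}}}glyphtype") or root.get("glyphtype") or ""
    defaults = _parse_defaults(root.get(f"{{{PARAMETRIC_NS}}}defaults", ""))

    paths: list[ParametricPath] = []
    markers: dict[str, ParametricPath] = {}
    for i, el in enumerate(root.iter()):
        if _local(el.tag) != "path":
            continue
        name = el.get("id") or f"path{i}"
        d = el.get("d")
        if d is None:
            raise GlyphValidationError(f"path {name!r} has no 'd' attribute")
        p = ParametricPath(
            name=name,
            static_d=d,
            parametric_d=el.get(f"{{{PARAMETRIC_NS}}}d"),
            style=Style.from_css(el.get("style", "")),
        )
        if name in MARKER_IDS:
            if name in markers:
                raise GlyphValidationError(f"duplicate marker path {name!r}")
            markers[name] = p
        else:
            paths.append(p)

    missing = [m for m in MARKER_IDS if m not in markers]
    if missing:
        raise GlyphValidationError(
            f"glyph is missing required marker path(s): {', '.join(missing)}"
        )
    glyph = GlyphDefinition(
        glyph_type=glyph_type,
        paths=paths,
        defaults=defaults,
        baseline=markers["baseline"],
        bounding_box=markers["bounding-box"],
    )
    if validate:
        glyph.validate()
    return glyph


# ---------------------------------------------------------------------------
# writing

def write_glyph(glyph: GlyphDefinition, file=None) -> str:
    """Serialize *glyph* to a pSVG document; refuses invalid glyphs.

    Stripping every ``parametric:*`` attribute from the output leaves a
    plain SVG that renders the default shape.
    """
    glyph.validate()
    box = glyph.box_bounds()
    root = ET.Element(
        f"{{{SVG_NS}}}svg",
        {
            "glyphtype": glyph.glyph_type,
            "viewBox": f"{box.xmin:g} {box.ymin:g} {box.width:g} {box.height:g}",
        },
    )
    if glyph.defaults:
        root.set(f"{{{PARAMETRIC_NS}}}defaults", _serialize_defaults(glyph.defaults))
    for p in glyph.paths:
        _write_path(root, p, p.style.to_css())
    _write_path(root, glyph.baseline, "fill:none;stroke:black;stroke-width:1")
    _write_path(
        root,
        glyph.bounding_box,
        "fill:none;stroke:gray;stroke-width:0.5;stroke-dasharray:2 2",
    )
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if file is not None:
        if isinstance(file, (str, os.PathLike)):
            Path(file).write_text(text)
        else:
            file.write(text)
    return text


def _write_path(root: ET.Element, p: ParametricPath, css: str) -> None:
    el = ET.SubElement(root, f"{{{SVG_NS}}}path", {"id": p.name, "d": p.static_d})
    if p.parametric_d is not None:
        el.set(f"{{{PARAMETRIC_NS}}}d", p.parametric_d)
    el.set("style", css)


def strip_parametric(text: str) -> str:
    """Remove every ``parametric:*`` attribute from a pSVG document string.

    The result is plain SVG with the baked path data untouched (backward
    compatibility guarantee).
    """
    root = ET.fromstring(text)
    prefix = f"{{{PARAMETRIC_NS}}}"
    for el in root.iter():
        for key in [k for k in el.attrib if k.startswith(prefix)]:
            del el.attrib[key]
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# library loading

def load_library(directory, strict: bool = True) -> GlyphLibrary:
    """Load every ``*.svg`` pSVG file in *directory* into a library.

    With ``strict=True`` (default) any invalid file aborts the load; with
    ``strict=False`` invalid files are reported to ``warnings`` and skipped.
    Duplicate glyph types and an empty directory are always errors.
    """
    import warnings

    directory = Path(directory)
    files = sorted(directory.glob("*.svg"))
    if not files:
        raise GlyphValidationError(f"no pSVG files found in {directory}")
    library = GlyphLibrary()
    for path in files:
        try:
            glyph = read_glyph(path)
        except GlyphValidationError as exc:
            if strict:
                raise GlyphValidationError(f"{path.name}: {exc}") from exc
            warnings.warn(f"skipping {path.name}: {exc}", stacklevel=2)
            continue
        library.add(glyph)
    if not len(library):
        raise GlyphValidationError(f"no valid pSVG files loaded from {directory}")
    return library
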