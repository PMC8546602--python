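"""Built-in parametric glyph library.

A representative subset of the SBOL Visual glyph set, generated
programmatically: the five sequence features used by the design shorthand
(Promoter, RBS, CDS, Terminator, RecombinationSite) and two molecular
species (Protein, SmallMolecule).

Conventions shared across the library:

* glyph coordinates use the SVG convention (y grows downward), the DNA
  baseline lies on ``y = 0`` and glyph bodies extend upward (negative y);
* every glyph exposes a ``width`` parameter and its baseline spans exactly
  ``[0, width]``, so composition is pure x-chaining;
* glyphs of similar construction share parameter names: all stem-and-head
  glyphs use ``width``/``height``, arrowed glyphs add ``arrowhead_width``
  (the CDS pentagon keeps its head fixed while the body stretches);
* default parameter values are chosen so the seven default shapes are
  visually distinct when composed on one baseline.
"""

from __future__ import annotations

from pathlib import Path

from .geometry import evaluate_template
from .model import GlyphDefinition, GlyphLibrary, ParametricPath, Style, write_glyph

__all__ = ["make_fixture_library", "write_fixture_library", "FIXTURE_GLYPH_TYPES"]

FIXTURE_GLYPH_TYPES = (
    "Promoter",
    "RBS",
    "CDS",
    "Terminator",
    "RecombinationSite",
    "Protein",
    "SmallMolecule",
)

_BASELINE_T = "M {0} {0} L {width} {0}"


def _glyph(glyph_type, defaults, paths, box_height_expr):
    """Assemble a glyph whose box is [0,width] x [-box_height, 0]."""
    box_t = (
        "M {0} {-(H)} L {width} {-(H)} L {width} {0} L {0} {0} Z".replace(
            "H", box_height_expr
        )
    )
    built = []
    for name, template, style in paths:
        built.append(
            ParametricPath(
                name=name,
                static_d=evaluate_template(template, defaults),
                parametric_d=template,
                style=style,
            )
        )
    glyph = GlyphDefinition(
        glyph_type=glyph_type,
        paths=built,
        defaults=dict(defaults),
        baseline=ParametricPath(
            "baseline", evaluate_template(_BASELINE_T, defaults), _BASELINE_T
        ),
        bounding_box=ParametricPath(
            "bounding-box", evaluate_template(box_t, defaults), box_t
        ),
    )
    glyph.validate()
    return glyph


def make_fixture_library() -> GlyphLibrary:
    """Build the built-in seven-glyph library in memory."""
    lib = GlyphLibrary()

    # CDS: pentagon arrow; body [0, width - arrowhead_width], fixed head.
    lib.add(
        _glyph(
            "CDS",
            {"width": 30.0, "height": 15.0, "arrowhead_width": 10.0},
            [
                (
                    "body",
                    "M {0} {0} L {0} {-height} L {width - arrowhead_width} {-height}"
                    " L {width} {-height/2} L {width - arrowhead_width} {0} Z",
                    Style(fill="#3cb371", stroke="black"),
                )
            ],
            "height",
        )
    )

    # Promoter: vertical stem with a right-pointing arrowed arm at the top.
    lib.add(
        _glyph(
            "Promoter",
            {
                "width": 12.0,
                "height": 15.0,
                "arrowhead_width": 4.0,
                "arrowhead_height": 3.0,
            },
            [
                ("stem", "M {0} {0} L {0} {-height}", Style()),
                (
                    "arm",
                    "M {0} {-height} L {width} {-height}"
                    " M {width - arrowhead_width} {-height + arrowhead_height}"
                    " L {width} {-height}"
                    " L {width - arrowhead_width} {-height - arrowhead_height}",
                    Style(),
                ),
            ],
            "height + arrowhead_height",
        )
    )

    # RBS: filled half-disc sitting on the baseline.
    lib.add(
        _glyph(
            "RBS",
            {"width": 12.0, "height": 6.0},
            [
                (
                    "body",
                    "M {0} {0} A {width/2} {height} 0 0 1 {width} {0} Z",
                    Style(fill="#4169e1", stroke="black"),
                )
            ],
            "height",
        )
    )

    # Terminator: centered stem capped by a horizontal bar (T shape).
    lib.add(
        _glyph(
            "Terminator",
            {"width": 10.0, "height": 12.0},
            [
                ("stem", "M {width/2} {0} L {width/2} {-height}", Style(stroke="#b22222")),
                ("bar", "M {0} {-height} L {width} {-height}", Style(stroke="#b22222")),
            ],
            "height",
        )
    )

    # Recombination site: solid triangle on the baseline.
    lib.add(
        _glyph(
            "RecombinationSite",
            {"width": 10.0, "height": 10.0},
            [
                (
                    "body",
                    "M {0} {0} L {width} {0} L {width/2} {-height} Z",
                    Style(fill="#ff8c00", stroke="black"),
                )
            ],
            "height",
        )
    )

    # Protein: circle (two half arcs) resting on the baseline.
    lib.add(
        _glyph(
            "Protein",
            {"width": 12.0, "height": 12.0},
            [
                (
                    "body",
                    "M {0} {-height/2}"
                    " A {width/2} {height/2} 0 0 1 {width} {-height/2}"
                    " A {width/2} {height/2} 0 0 1 {0} {-height/2} Z",
                    Style(fill="#9370db", stroke="black"),
                )
            ],
            "height",
        )
    )

    # Small molecule: open diamond touching the baseline.
    lib.add(
        _glyph(
            "SmallMolecule",
            {"width": 8.0, "height": 8.0},
            [
                (
                    "body",
                    "M {0} {-height/2} L {width/2} {-height} L {width} {-height/2}"
                    " L {width/2} {0} Z",
                    Style(fill=None, stroke="black"),
                )
            ],
            "height",
        )
    )
    return lib


def write_fixture_library(directory) -> list[Path]:
    """Write the built-in library as pSVG files under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for glyph in make_fixture_library():
        path = directory / f"{glyph.glyph_type.lower()}.svg"
        write_glyph(glyph, path)
        written.append(path)
    return written
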