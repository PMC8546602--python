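# sbolv

Rendering of SBOL Visual (SBOLv) genetic design diagrams from **parametric
SVG (pSVG)** glyph definitions.

SBOLv is the community standard set of glyphs for drawing engineered
genetic designs: promoters, ribosome binding sites, coding sequences,
terminators and so on, composed left to right on a DNA baseline.  Tools
that draw these diagrams traditionally hard-code one rendering function
per glyph, which becomes a maintenance burden as the glyph set grows and
changes.  This package takes the opposite approach: each glyph lives in a
machine-readable pSVG file — an ordinary SVG extended with parametric
attributes — and a single rendering pipeline serves every glyph.

A pSVG path stores its default shape in the standard `d` attribute (so any
SVG viewer can render it) and a template in a `parametric:d` attribute in
which coordinates are arithmetic expressions over named parameters:

```xml
<svg xmlns="http://www.w3.org/2000/svg"
     xmlns:parametric="urn:sbolv:parametric"
     glyphtype="CDS"
     parametric:defaults="width=30;height=15;arrowhead_width=10">
  <path id="body"
        d="M 0 0 L 0 -15 L 20 -15 L 30 -7.5 L 20 0 Z"
        parametric:d="M {0} {0} L {0} {-height}
                      L {width - arrowhead_width} {-height}
                      L {width} {-height/2}
                      L {width - arrowhead_width} {0} Z"/>
  <path id="baseline" d="M 0 0 L 30 0" parametric:d="M {0} {0} L {width} {0}"/>
  <path id="bounding-box" d="M 0 -15 L 30 -15 L 30 0 L 0 0 Z" .../>
</svg>
```

Evaluating the templates at user-supplied parameter values customizes the
geometry in exactly the ways the standard allows: widening this CDS
stretches the arrow's *body* (`width - arrowhead_width`) while the head
keeps its shape.  Two special paths encode the composition contract: the
**baseline** (the DNA strand; its start is the glyph's anchor, its end is
where the next glyph goes) and the **bounding box** (the space the glyph
occupies).

On top of the format the package provides:

* an expression engine (`+ - * /`, parentheses, `sin cos tan sqrt abs
  min max`, radians) and an SVG path-data evaluator with tight bounds
  computation (`M L C Q A Z`, curve extrema, arcs via cubic conversion);
* `GlyphRenderer` — draw one glyph at an anchor with `user_parameters`
  (geometry) and `user_style` (per-path fill/stroke) overrides, returning
  the drawn bounds and the baseline end point;
* construct layout — chain parts along a shared baseline, route
  regulatory interaction arcs (inhibition ⊣, control ◇, stimulation →)
  with deterministic stacking, and wrap long designs across rows;
* a design shorthand (`p r c.blue <t` plus interactions like
  `0//2//in//red`) and a GenBank converter that draws coding regions at
  correct relative sizes with function-based coloring;
* a bundled seven-glyph parametric library (Promoter, RBS, CDS,
  Terminator, RecombinationSite, Protein, SmallMolecule) generated
  programmatically and written to disk with `sbolv glyphs init <dir>`.

## Worked example

```python
import sbolv

lib = sbolv.make_fixture_library()
renderer = sbolv.GlyphRenderer(lib)
canvas = sbolv.SVGCanvas()
result = renderer.draw_glyph(
    "CDS",
    anchor=(0, 0),
    user_parameters={"width": 60},          # stretch the body, not the head
    user_style={"body": {"fill": "tomato"}},
    canvas=canvas,
)
print("bounds:", result.bounds)
print("baseline_end:", result.baseline_end)
open("cds.svg", "w").write(canvas.finalize())
```

prints

```
bounds: Bounds(xmin=0.0, ymin=-15.0, xmax=60.0, ymax=0.0)
baseline_end: (60.0, 0)
```

The glyph is 60 units wide (doubled from the default 30) but its
arrowhead still spans 10 units; `baseline_end` is where the next part of
a construct would be anchored.  The same diagram from the shell:

```sh
sbolv draw --string "p r c.l_blue <t" --interaction "0//2//in//red" --output design.svg
sbolv genbank-fixture --n-cds 12 --seed 1 --output demo.gb
sbolv genbank --input demo.gb --line-width 150 --output demo.svg
```

`design.svg` contains a promoter, an RBS, a light-blue CDS and a reversed
terminator on one backbone, with a red inhibition arc (ending in a
perpendicular bar) from the promoter to the CDS.

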