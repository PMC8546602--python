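# Methods

## The pSVG dialect

A pSVG glyph file is a standard SVG document plus attributes in the
`urn:sbolv:parametric` namespace.  The normative choices of this
implementation:

* **Templates.** Each `path` element may carry a `parametric:d` attribute:
  ordinary SVG path data in which any number may be replaced by an
  `{expression}` in curly braces.  Braces do not nest.  Numbers written
  bare inside a template are allowed and pass through unchanged.
* **Defaults.** The root `svg` element carries `parametric:defaults`,
  semicolon-separated `name=value` pairs.  Defaults must bind every
  parameter referenced by any template in the file (closure), so a glyph
  always renders without user input.
* **Identity.** The static `d` of a path must equal its template
  evaluated at the defaults, coordinate-wise to `1e-9`.  This is what
  makes the file backward compatible: an SVG consumer that ignores the
  parametric attributes renders exactly the default shape.
* **Markers.** Two reserved path ids encode composition metadata:
  `baseline` (a horizontal segment; `y_start == y_end`, spanning the
  bounding box horizontally) and `bounding-box` (a rectangle containing
  all geometry evaluated at defaults, tolerance `1e-6`).  They are
  written to files (visible to generic viewers, as in hand-drawn glyph
  schematics) but never painted when the glyph is rendered onto a canvas.
* **Naming.** The SVG `id` attribute is the path name addressed by style
  overrides; the SBOLv term lives in a root `glyphtype` attribute.
* **Coordinates.** SVG screen convention throughout: y grows downward,
  so glyph bodies above the DNA baseline have negative y.  Bounds are
  closed intervals.

## Expression engine

Infix grammar with `+ - * /`, parentheses, unary minus (binding tighter
than `*`/`/`), left associativity, and the fixed function table `sin cos
tan sqrt abs` (unary) and `min max` (binary); angles in radians; decimal
literals with optional fraction/exponent; whitespace insignificant.  The
published format description promises "basic arithmetic or trigonometric
functions" without enumerating them; this table is the smallest set that
covers the bundled glyphs with obvious room for curved shapes.  Unknown
parameters are reported at evaluation time (a library must parse before
any bindings exist); division by zero is an error, never an infinity.
Evaluation is plain recursive descent over a frozen AST — identical text
and binding give bit-identical results.

## Path geometry

Supported opcodes are the absolute `M L C Q A Z`; relative lowercase
forms are normalized on input (tracking the current point and subpath
start; a repeated `M` continues as `L` per the SVG specification).  The
`H V S T` shorthands are excluded — the bundled glyphs avoid them and the
evaluator stays small.  Numbers are serialized with up to nine
significant digits, falling back to the shortest exact decimal whenever
nine digits would not round-trip, so parse∘serialize is the identity and
the `1e-9` default-identity tolerance is meaningful.

Bounds are exact for polylines, use derivative extremum analysis for
cubics (quadratics are degree-elevated first), and convert elliptical
arcs to cubic segments of at most a quarter turn (the classic
`4/3·tan(Δθ/4)` control-point construction), which keeps one bounding
code path; the approximation error of a quarter-circle cubic is below
`3e-4` of the radius and the dense-sampling oracle test pins it below
`1e-6` of the curve span for the shapes used here.  Affine transforms map
arc commands exactly when the transform is a similarity (radii scaled
uniformly, axis direction mapped through the linear part, sweep flag
flipped on reflection); a general affine converts arcs to cubics first.
Half-turn rotations are built as exact point reflections (no
trigonometry) so the reverse-orientation involution holds to machine
precision.

## Rendering and composition

`resolve_parameters` overlays user values on the defaults and rejects
unknown keys by name.  Drawing translates the evaluated geometry so the
baseline start sits on the anchor; **reverse orientation rotates the
geometry 180° about the midpoint of its own baseline** before
translation.  The published notation only says a prefix "reverses the
direction of the part"; rotation (rather than a vertical-axis mirror) is
the SBOLv convention for reverse-strand parts — it flips the glyph below
the baseline — and it preserves the baseline extent, which is what makes
reverse parts layout-neutral.  The returned `RenderResult` carries the
union bounds of the painted geometry (not the declared box, so bounds
respond to parameter changes) plus the baseline start and end.

The SVG canvas is a painter's model; emitted paths carry ids
`<glyph_type>.<path_name>.<instance_index>` for structural inspection,
and the document view box is the union of drawn bounds padded by a margin
(default 5 units).  Colors are CSS named colors or hex triplets,
normalized to hex; anything else is an error.

## Construct layout

Part anchors chain as `anchor(i+1).x = baseline_end(i).x +
part_spacing` — stated in this reconstruction form because it is exact in
floating point, whereas the equivalent subtraction `anchor(i+1).x −
baseline_end(i).x` can differ from the spacing by one ulp.  A continuous
backbone line is drawn beneath each row (standard SBOLv presentation).

Interaction arcs run from above the source part's bounds center to above
the target's, with apex clearance `base_clearance_factor × (tallest glyph
height in the span)` plus `level_step` (default 6 units) per previously
routed arc whose part-index span overlaps this one — processed in input
order, so stacking is deterministic.  Terminal decorations: inhibition =
bar perpendicular to the vertical approach, control = open diamond,
stimulation = open arrowhead (included for SBOLv completeness; the
shorthand exposes only `in` and `co`).

Wrapping is greedy left-to-right fill against `max_line_width`: a part
starts a new row when it would overflow, unless it would be the row's
first part (oversized parts get their own row).  Rows sit `line_spacing`
apart.  An interaction whose endpoints land on different rows is drawn in
the source part's row and truncated at the row edge without a decoration
— a documented convention; nothing in the source notation prescribes
cross-row arc geometry.

## Shorthand and GenBank front-ends

Shorthand micro-syntax (delimiters are this package's choice; the
published notation shows only the vocabulary): whitespace-separated
tokens, `<` prefix for reverse, `.color` suffix for fill; interactions
are one `start//end//type//color` string each, repeatable.  `l_` colors
blend the base color 50% toward white per RGB channel (rounded), which is
channel-wise nondecreasing and easy to verify.  The token color is
applied to the fill of the glyph's primary (first) path, and to its
stroke as well when that path is stroke-only, so promoters and
terminators still show their color.

GenBank conversion retains `CDS` features (configurable), orders them by
start coordinate, and sets `width_hint = max(min_width, length × scale)`
with 1-based inclusive lengths; compound (joined) locations use the
overall span.  Defaults: `scale = 0.02` canvas units per nucleotide (20
units/kb, so a typical ~1 kb gene is about as wide as two default CDS
glyphs) and `min_width = 8` so short genes stay visible.  Colors come
from the first matching case-insensitive substring rule against
`/product` and `/function`, else neutral gray `#c8c8c8`.  Intergenic
gaps are *not* to scale: only coding-region widths are proportional.

## Synthetic test records

`make_synthetic_record(n_cds, seed)` emulates an annotated bacterial
genome fragment: CDS lengths uniform over one-third to five-thirds of the
mean (default mean 900 nt, multiples of 3), 60% forward strand,
intergenic gaps of 20–400 nt, products cycled through a small vocabulary
of annotations.  It reproduces the properties the renderer depends on —
coordinates, strands, qualifier text — but none of the biology real
records carry (no codon structure, no overlapping or nested features, no
joined locations, no pseudo-genes), so passing tests demonstrate correct
geometry and mapping, not robustness to every GenBank corner case.

## Numerical choices and limitations

* Tolerances: `1e-9` default-evaluation identity; `1e-6` bounding-box
  containment and curve-bounds accuracy; involutions hold to `<1e-12` in
  practice and are asserted at `1e-9`.
* The acceptance script uses its own reimplementation of the random
  expression generator and a Python-`eval` oracle so the check stays
  independent of the package's parser.
* Problem sizes in tests and the acceptance script (1000 random
  expressions, 100 random constructs, 200 shorthand round trips, 12-CDS
  records) are the sizes at which every property is already
  exercised across all code paths; all runs complete in seconds.
* Not covered by design: the full official SBOLv catalogue (the format
  supports it; seven representative glyphs are bundled), CSS stylesheets
  beyond inline `style` attributes, stroke-width-aware bounds, circular
  (plasmid) layouts, crossing minimization for arcs, and inference of
  non-CDS glyphs from GenBank annotations.
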