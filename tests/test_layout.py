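"""Construct layout: baseline chaining, arc routing, wrapping, full render."""

import random
import xml.etree.ElementTree as ET

import pytest

from sbolv.errors import LayoutError
from sbolv.geometry import path_bounds
from sbolv.layout import (
    ConstructSpec,
    Interaction,
    Part,
    layout_parts,
    render_construct,
    route_interaction,
    wrap_lines,
)
from sbolv.render import SVGCanvas

SVG_NS = "{http://www.w3.org/2000/svg}"


def cds(width, orientation="forward"):
    return Part(glyph_type="CDS", orientation=orientation, width_hint=width)


# ---------------------------------------------------------------------------
# chaining


def test_anchor_chaining_arithmetic(lib):
    spec = ConstructSpec(
        parts=(cds(30), cds(20), cds(40)), part_spacing=5.0, start=(0, 0)
    )
    placed = layout_parts(spec, lib)
    assert [p.anchor[0] for p in placed] == [0, 35, 60]
    assert placed[-1].result.baseline_end == (100, 0)


def test_empty_layout(lib):
    assert layout_parts(ConstructSpec(parts=()), lib) == []


def test_reverse_part_does_not_shift_anchors(lib):
    forward = ConstructSpec(parts=(cds(30), cds(20), cds(40)), part_spacing=5)
    mixed = ConstructSpec(
        parts=(cds(30), cds(20, "reverse"), cds(40)), part_spacing=5
    )
    assert [p.anchor for p in layout_parts(mixed, lib)] == [
        p.anchor for p in layout_parts(forward, lib)
    ]


def test_chaining_property_random_specs(lib):
    """anchor(i+1).x - baseline_end(i).x == spacing exactly; y constant."""
    rng = random.Random(2024)
    types = ["Promoter", "RBS", "CDS", "Terminator", "RecombinationSite"]
    for _ in range(100):
        n = rng.randrange(1, 11)
        parts = tuple(
            Part(
                glyph_type=rng.choice(types),
                orientation=rng.choice(["forward", "reverse"]),
            )
            for _ in range(n)
        )
        spacing = rng.choice([0.0, 1.5, 4.0, 10.0])
        start = (rng.uniform(-50, 50), rng.uniform(-50, 50))
        placed = layout_parts(
            ConstructSpec(parts=parts, part_spacing=spacing, start=start), lib
        )
        for prev, nxt in zip(placed, placed[1:]):
            assert nxt.anchor[0] == prev.result.baseline_end[0] + spacing
        assert {p.anchor[1] for p in placed} == {start[1]}


def test_total_width_is_sum_of_spans_plus_gaps(lib):
    widths = [12.0, 33.5, 20.0, 47.25]
    spec = ConstructSpec(parts=tuple(cds(w) for w in widths), part_spacing=3.0)
    placed = layout_parts(spec, lib)
    total = placed[-1].result.baseline_end[0] - placed[0].anchor[0]
    assert total == pytest.approx(sum(widths) + 3.0 * (len(widths) - 1))


def test_width_hint_requires_width_parameter(lib):
    part = Part(glyph_type="Protein", width_hint=50)
    part2 = Part(glyph_type="CDS", width_hint=50)
    # Protein does define width, so hint applies; fake a glyph without one
    placed = layout_parts(ConstructSpec(parts=(part, part2)), lib)
    assert placed[0].result.baseline_span == 50


# ---------------------------------------------------------------------------
# interaction validation and routing


def test_interaction_validation():
    with pytest.raises(LayoutError):
        Interaction(1, 1, "inhibition")
    with pytest.raises(LayoutError):
        Interaction(0, 1, "repression")
    with pytest.raises(LayoutError):
        ConstructSpec(parts=(cds(10),), interactions=(Interaction(0, 5, "control"),))


def test_single_arc_spans_all_parts(lib):
    spec = ConstructSpec(parts=(cds(30), cds(30), cds(30)), part_spacing=5)
    placed = layout_parts(spec, lib)
    arc = route_interaction(Interaction(0, 2, "inhibition"), placed, spec)
    assert arc.level == 0
    apex_y = arc.spine[1].args[1]
    # clears 1.2 x the tallest glyph in the span (CDS height 15)
    assert apex_y == pytest.approx(-1.2 * 15)
    assert arc.spine[0].args[0] == pytest.approx(placed[0].result.bounds.center[0])
    assert arc.spine[-1].args[0] == pytest.approx(placed[2].result.bounds.center[0])


def test_overlapping_arcs_stack_one_level_apart(lib):
    spec = ConstructSpec(parts=(cds(30), cds(30), cds(30)), part_spacing=5)
    placed = layout_parts(spec, lib)
    first = Interaction(0, 2, "inhibition")
    second = Interaction(1, 2, "control")
    arc1 = route_interaction(first, placed, spec, routed=())
    arc2 = route_interaction(second, placed, spec, routed=(first,))
    assert arc1.level == 0 and arc2.level == 1
    assert arc1.spine[1].args[1] - arc2.spine[1].args[1] == pytest.approx(
        spec.level_step
    )


def test_disjoint_arcs_share_level(lib):
    spec = ConstructSpec(parts=(cds(20),) * 4, part_spacing=5)
    placed = layout_parts(spec, lib)
    first = Interaction(0, 1, "control")
    arc2 = route_interaction(Interaction(2, 3, "control"), placed, spec, (first,))
    assert arc2.level == 0


def test_arc_stacking_deterministic(lib):
    spec = ConstructSpec(
        parts=(cds(20),) * 5,
        part_spacing=5,
        interactions=(
            Interaction(0, 4, "inhibition"),
            Interaction(1, 3, "control"),
            Interaction(2, 4, "stimulation"),
        ),
    )
    def levels():
        placed = layout_parts(spec, lib)
        routed = []
        out = []
        for i in spec.interactions:
            out.append(route_interaction(i, placed, spec, tuple(routed)).level)
            routed.append(i)
        return out

    assert levels() == levels() == [0, 1, 2]


def test_inhibition_terminal_is_perpendicular_bar(lib):
    spec = ConstructSpec(parts=(cds(30), cds(30)), part_spacing=5)
    placed = layout_parts(spec, lib)
    arc = route_interaction(Interaction(0, 1, "inhibition"), placed, spec)
    assert arc.decoration_name == "bar"
    (x0, y0), (x1, y1) = arc.decoration[0].args, arc.decoration[1].args
    assert y0 == y1  # horizontal bar, perpendicular to the vertical approach
    assert x1 != x0


# ---------------------------------------------------------------------------
# wrapping


def test_greedy_wrap(lib):
    spec = ConstructSpec(
        parts=(cds(30), cds(30), cds(30)), part_spacing=0, max_line_width=70
    )
    rows = wrap_lines(spec, lib)
    assert [len(r) for r in rows] == [2, 1]


def test_oversized_part_gets_own_row(lib):
    spec = ConstructSpec(parts=(cds(200),), max_line_width=100)
    rows = wrap_lines(spec, lib)
    assert [len(r) for r in rows] == [1]


def test_wrap_conserves_order_and_fits(lib):
    rng = random.Random(5)
    widths = [round(rng.uniform(5, 60), 2) for _ in range(100)]
    spacing, max_width = 2.0, 90.0
    spec = ConstructSpec(
        parts=tuple(cds(w) for w in widths),
        part_spacing=spacing,
        max_line_width=max_width,
    )
    rows = wrap_lines(spec, lib)
    flattened = [p.width_hint for row in rows for p in row]
    assert flattened == widths
    for row in rows:
        row_width = sum(p.width_hint for p in row) + spacing * (len(row) - 1)
        assert row_width <= max_width or len(row) == 1


def test_wrap_matches_brute_force_resimulation(lib):
    rng = random.Random(17)
    widths = [round(rng.uniform(5, 60), 2) for _ in range(60)]
    spacing, max_width = 3.0, 100.0
    spec = ConstructSpec(
        parts=tuple(cds(w) for w in widths),
        part_spacing=spacing,
        max_line_width=max_width,
    )
    got = [[p.width_hint for p in row] for row in wrap_lines(spec, lib)]
    expected, current, x = [], [], 0.0
    for w in widths:
        end = (x + spacing if current else 0.0) + w
        if current and end > max_width:
            expected.append(current)
            current, x = [w], w
        else:
            current.append(w)
            x = end
    if current:
        expected.append(current)
    assert got == expected


# ---------------------------------------------------------------------------
# full render


def test_render_shorthand_style_construct(lib):
    spec = ConstructSpec(
        parts=(
            Part("Promoter"),
            Part("RBS"),
            Part("CDS"),
            Part("Terminator"),
        ),
        interactions=(Interaction(0, 2, "inhibition", "red"),),
    )
    canvas = SVGCanvas()
    render_construct(spec, lib, canvas)
    root = ET.fromstring(canvas.finalize())
    ids = [el.get("id") for el in root.iter(f"{SVG_NS}path")]
    glyph_ids = [i for i in ids if i.split(".")[0] in
                 ("Promoter", "RBS", "CDS", "Terminator")]
    assert len({i.rsplit(".", 1)[-1] for i in glyph_ids}) == 4  # 4 instances
    assert "interaction.inhibition.0" in ids
    assert "interaction.inhibition.0.bar" in ids
    assert "backbone.0" in ids


def test_render_empty_spec(lib):
    canvas = SVGCanvas()
    bounds = render_construct(ConstructSpec(parts=()), lib, canvas)
    assert bounds.width == 0 and bounds.height == 0
    ET.fromstring(canvas.finalize())


def test_wrapped_rows_spaced_by_line_spacing(lib):
    spec = ConstructSpec(
        parts=(cds(30), cds(30), cds(30)),
        part_spacing=0,
        max_line_width=70,
        line_spacing=45.0,
    )
    canvas = SVGCanvas()
    render_construct(spec, lib, canvas)
    root = ET.fromstring(canvas.finalize())
    backbones = {
        el.get("id"): el.get("d")
        for el in root.iter(f"{SVG_NS}path")
        if el.get("id").startswith("backbone.")
    }
    assert set(backbones) == {"backbone.0", "backbone.1"}
    y0 = float(backbones["backbone.0"].split()[2])
    y1 = float(backbones["backbone.1"].split()[2])
    assert y1 - y0 == pytest.approx(45.0)


def test_cross_row_interaction_truncated_without_decoration(lib):
    spec = ConstructSpec(
        parts=(cds(30), cds(30), cds(30)),
        part_spacing=0,
        max_line_width=70,
        interactions=(Interaction(0, 2, "inhibition"),),
    )
    canvas = SVGCanvas()
    render_construct(spec, lib, canvas)
    svg = canvas.finalize()
    assert "interaction.inhibition.0" in svg
    assert "interaction.inhibition.0.bar" not in svg
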