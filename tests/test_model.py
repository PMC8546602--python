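"""pSVG document model: reading, writing, validation, library loading."""

import random
import xml.etree.ElementTree as ET

import pytest

from sbolv.errors import GlyphValidationError
from sbolv.fixtures import FIXTURE_GLYPH_TYPES, make_fixture_library, write_fixture_library
from sbolv.geometry import evaluate_template, parse_path_data
from sbolv.model import (
    PARAMETRIC_NS,
    GlyphDefinition,
    ParametricPath,
    Style,
    load_library,
    read_glyph,
    strip_parametric,
    write_glyph,
)

BASELINE = ParametricPath("baseline", "M 0 0 L 30 0", "M {0} {0} L {width} {0}")
BOX = ParametricPath(
    "bounding-box",
    "M 0 -15 L 30 -15 L 30 0 L 0 0 Z",
    "M {0} {-height} L {width} {-height} L {width} {0} L {0} {0} Z",
)


def simple_glyph(**overrides) -> GlyphDefinition:
    fields = dict(
        glyph_type="CDS",
        paths=[
            ParametricPath(
                "body",
                "M 0 0 L 0 -15 L 20 -15 L 30 -7.5 L 20 0 Z",
                "M {0} {0} L {0} {-height} L {width - arrowhead_width} {-height}"
                " L {width} {-height/2} L {width - arrowhead_width} {0} Z",
                Style(fill="#3cb371"),
            )
        ],
        defaults={"width": 30.0, "height": 15.0, "arrowhead_width": 10.0},
        baseline=BASELINE,
        bounding_box=BOX,
    )
    fields.update(overrides)
    return GlyphDefinition(**fields)


# ---------------------------------------------------------------------------
# validation


def test_valid_glyph_passes():
    simple_glyph().validate()


def test_missing_default_is_closure_violation():
    glyph = simple_glyph(defaults={"height": 15.0, "arrowhead_width": 10.0})
    with pytest.raises(GlyphValidationError, match="'width'"):
        glyph.validate()


def test_static_parametric_mismatch_reports_deviation():
    glyph = simple_glyph()
    bad = ParametricPath(
        "body",
        "M 0 0 L 0 -15 L 20 -15 L 30 -7.5 L 21 0 Z",  # one coordinate off by 1
        glyph.paths[0].parametric_d,
    )
    with pytest.raises(GlyphValidationError, match="max deviation"):
        simple_glyph(paths=[bad]).validate()


def test_duplicate_path_names_refused():
    glyph = simple_glyph(paths=[simple_glyph().paths[0]] * 2)
    with pytest.raises(GlyphValidationError, match="duplicate"):
        write_glyph(glyph)


def test_non_horizontal_baseline_refused():
    baseline = ParametricPath("baseline", "M 0 0 L 30 -2", "M {0} {0} L {width} {-2}")
    with pytest.raises(GlyphValidationError, match="horizontal"):
        simple_glyph(baseline=baseline).validate()


def test_geometry_outside_bounding_box_refused():
    box = ParametricPath(
        "bounding-box",
        "M 0 -10 L 30 -10 L 30 0 L 0 0 Z",
        "M {0} {-10} L {width} {-10} L {width} {0} L {0} {0} Z",
    )
    with pytest.raises(GlyphValidationError, match="bounding box"):
        simple_glyph(bounding_box=box).validate()


# ---------------------------------------------------------------------------
# reading


def test_read_fixture_promoter_file(tmp_path):
    write_fixture_library(tmp_path)
    glyph = read_glyph(tmp_path / "promoter.svg")
    assert glyph.glyph_type == "Promoter"
    assert glyph.path_names() == ["stem", "arm"]
    assert glyph.defaults["width"] == 12.0


def test_read_rejects_closure_violation():
    text = write_glyph(simple_glyph())
    broken = text.replace("width=30;", "")
    with pytest.raises(GlyphValidationError, match="'width'"):
        read_glyph(broken)


def test_read_plain_svg_without_parametric_attributes():
    """A degenerate pSVG: plain d attributes plus the two marker paths."""
    text = """<svg xmlns="http://www.w3.org/2000/svg" glyphtype="Thing">
      <path id="body" d="M 0 0 L 10 0 L 5 -8 Z" style="fill:gray"/>
      <path id="baseline" d="M 0 0 L 10 0"/>
      <path id="bounding-box" d="M 0 -8 L 10 -8 L 10 0 L 0 0 Z"/>
    </svg>"""
    glyph = read_glyph(text)
    assert glyph.defaults == {}
    assert all(p.parametric_d is None for p in glyph.paths)
    assert glyph.glyph_type == "Thing"


def test_read_requires_markers():
    text = """<svg xmlns="http://www.w3.org/2000/svg">
      <path id="body" d="M 0 0 L 10 0"/></svg>"""
    with pytest.raises(GlyphValidationError, match="baseline"):
        read_glyph(text)


# ---------------------------------------------------------------------------
# writing and round trips


def _semantically_equal(a: GlyphDefinition, b: GlyphDefinition) -> bool:
    if a.glyph_type != b.glyph_type or a.defaults != b.defaults:
        return False
    for pa, pb in zip(a._all_paths(), b._all_paths(), strict=True):
        if pa.name != pb.name or pa.parametric_d != pb.parametric_d:
            return False
        if parse_path_data(pa.static_d) != parse_path_data(pb.static_d):
            return False
    return True


def test_round_trip_every_fixture_glyph():
    for glyph in make_fixture_library():
        assert _semantically_equal(glyph, read_glyph(write_glyph(glyph)))


def test_round_trip_random_glyphs():
    """Randomly sized single-path glyphs survive write/read unchanged."""
    rng = random.Random(11)
    template = (
        "M {0} {0} L {0} {-height} L {width} {-height} L {width} {0} Z"
    )
    for i in range(50):
        defaults = {
            "width": round(rng.uniform(5, 80), 3),
            "height": round(rng.uniform(5, 40), 3),
        }
        glyph = GlyphDefinition(
            glyph_type=f"Box{i}",
            paths=[
                ParametricPath(
                    "body", evaluate_template(template, defaults), template
                )
            ],
            defaults=defaults,
            baseline=ParametricPath(
                "baseline",
                evaluate_template("M {0} {0} L {width} {0}", defaults),
                "M {0} {0} L {width} {0}",
            ),
            bounding_box=ParametricPath(
                "bounding-box", evaluate_template(template, defaults), template
            ),
        )
        assert _semantically_equal(glyph, read_glyph(write_glyph(glyph)))


def test_backward_compatibility_stripping():
    """Removing parametric:* attributes leaves plain SVG with identical d data."""
    for glyph in make_fixture_library():
        full = write_glyph(glyph)
        stripped = strip_parametric(full)
        root = ET.fromstring(stripped)  # generic parse must succeed
        assert PARAMETRIC_NS not in stripped
        svg_ns = "{http://www.w3.org/2000/svg}"
        by_id = {
            el.get("id"): el.get("d") for el in root.iter(f"{svg_ns}path")
        }
        for p in glyph._all_paths():
            assert by_id[p.name] == p.static_d


# ---------------------------------------------------------------------------
# library loading


def test_load_fixture_directory(tmp_path):
    write_fixture_library(tmp_path)
    library = load_library(tmp_path)
    assert len(library) == 7
    assert set(library.types()) == set(FIXTURE_GLYPH_TYPES)


def test_duplicate_glyph_type_error(tmp_path):
    text = write_glyph(simple_glyph())
    (tmp_path / "a.svg").write_text(text)
    (tmp_path / "b.svg").write_text(text)
    with pytest.raises(GlyphValidationError, match="duplicate glyph type"):
        load_library(tmp_path)


def test_empty_directory_error(tmp_path):
    with pytest.raises(GlyphValidationError, match="no pSVG files"):
        load_library(tmp_path)


def test_non_strict_load_skips_invalid_files(tmp_path):
    write_fixture_library(tmp_path)
    (tmp_path / "broken.svg").write_text("<svg xmlns='http://www.w3.org/2000/svg'/>")
    with pytest.raises(GlyphValidationError):
        load_library(tmp_path, strict=True)
    with pytest.warns(UserWarning, match="broken.svg"):
        library = load_library(tmp_path, strict=False)
    assert len(library) == 7
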