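"""GenBank front-end: annotated records to wrapped glyph diagrams.

Coding sequences from a GenBank record become CDS glyphs whose widths are
proportional to feature length (``width = max(min_width, length * scale)``,
lengths in nucleotides, 1-based inclusive GenBank coordinates), whose
orientation follows the strand, and whose fill color comes from the first
matching qualifier rule (case-insensitive substring match against
``/product`` and ``/function``), falling back to a neutral gray.  Long
records wrap across rows reading left-to-right, top-to-bottom; intergenic
gaps are not drawn to scale (parts are packed at uniform spacing).
"""

from __future__ import annotations

import io
import os
import random
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import SbolvError
from .geometry import Bounds
from .layout import ConstructSpec, Part, render_construct
from .model import GlyphLibrary
from .render import Canvas

__all__ = [
    "ColorRule",
    "FeatureMapping",
    "genbank_to_parts",
    "render_genbank",
    "make_synthetic_record",
    "read_color_rules",
]

DEFAULT_COLOR = "#c8c8c8"  # neutral gray for features no rule matches


@dataclass(frozen=True)
class ColorRule:
    """Case-insensitive substring pattern against /product and /function."""

    pattern: str
    color: str


@dataclass(frozen=True)
class FeatureMapping:
    """How GenBank features map onto glyph parts."""

    retained_keys: tuple[str, ...] = ("CDS",)
    rules: tuple[ColorRule, ...] = ()
    scale: float = 0.02  # canvas units per nucleotide (20 units/kb)
    min_width: float = 8.0
    default_color: str = DEFAULT_COLOR
    qualifiers: tuple[str, ...] = ("product", "function")

    def __post_init__(self):
        if self.scale <= 0:
            raise SbolvError("scale must be positive")
        if self.min_width <= 0:
            raise SbolvError("min_width must be positive")

    def color_for(self, feature: SeqFeature) -> str:
        """First matching rule wins; default gray otherwise."""
        texts = []
        for q in self.qualifiers:
            texts.extend(str(v).lower() for v in feature.qualifiers.get(q, []))
        for rule in self.rules:
            pat = rule.pattern.lower()
            if any(pat in t for t in texts):
                return rule.color
        return self.default_color


def _load_record(record) -> SeqRecord:
    if isinstance(record, SeqRecord):
        return record
    if isinstance(record, (str, os.PathLike)) and not str(record).lstrip().startswith(
        "LOCUS"
    ):
        source = Path(record)
    else:
        source = io.StringIO(str(record))
    try:
        return SeqIO.read(source, "genbank")
    except Exception as exc:
        raise SbolvError(f"cannot parse GenBank input: {exc}") from exc


def _feature_span(feature: SeqFeature) -> tuple[int, int]:
    """(start, length) with length in 1-based inclusive GenBank terms.

    Compound (joined) locations use the overall span from the minimum
    start to the maximum end.
    """
    start = int(feature.location.start)
    end = int(feature.location.end)
    return start, end - start  # Biopython end is exclusive: == gb end-start+1


def genbank_to_parts(record, mapping: FeatureMapping | None = None) -> list[Part]:
    """One part per retained feature, ordered by start coordinate.

    A record with no retained feature yields an empty list and a warning.
    """
    mapping = mapping or FeatureMapping()
    rec = _load_record(record)
    retained = [f for f in rec.features if f.type in mapping.retained_keys]
    if not retained:
        warnings.warn(
            f"record {rec.id!r} has no feature of type "
            f"{'/'.join(mapping.retained_keys)}",
            stacklevel=2,
        )
        return []
    retained.sort(key=lambda f: _feature_span(f)[0])
    parts = []
    for feature in retained:
        _, length = _feature_span(feature)
        width = max(mapping.min_width, length * mapping.scale)
        label = None
        if feature.qualifiers.get("gene"):
            label = str(feature.qualifiers["gene"][0])
        parts.append(
            Part(
                glyph_type="CDS",
                orientation="reverse" if feature.location.strand == -1 else "forward",
                user_style={"body": {"fill": mapping.color_for(feature)}},
                width_hint=width,
                label=label,
            )
        )
    return parts


def render_genbank(
    record,
    mapping: FeatureMapping | None,
    lib: GlyphLibrary,
    canvas: Canvas,
    max_line_width: float | None = 300.0,
    part_spacing: float = 4.0,
    line_spacing: float = 40.0,
) -> Bounds:
    """Convert a record to parts and render the wrapped construct."""
    parts = genbank_to_parts(record, mapping)
    spec = ConstructSpec(
        parts=tuple(parts),
        part_spacing=part_spacing,
        max_line_width=max_line_width,
        line_spacing=line_spacing,
    )
    return render_construct(spec, lib, canvas)


def read_color_rules(source) -> tuple[ColorRule, ...]:
    """Read ``pattern=color`` lines (``#`` comments and blanks ignored)."""
    if isinstance(source, (str, os.PathLike)):
        text = Path(source).read_text()
    else:
        text = source.read()
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SbolvError(f"color rule line {lineno}: expected pattern=color")
        pattern, color = line.split("=", 1)
        rules.append(ColorRule(pattern.strip(), color.strip()))
    return tuple(rules)


_PRODUCTS = (
    "DNA polymerase",
    "RNA polymerase",
    "ribosomal protein",
    "ABC transporter",
    "protein kinase",
    "hypothetical protein",
)


def make_synthetic_record(
    n_cds: int = 12, seed: int = 0, mean_length: int = 900
) -> SeqRecord:
    """Deterministic synthetic GenBank record for tests and demos.

    Alternating-ish strands, lengths drawn uniformly in
    ``[mean_length/3, 5*mean_length/3]`` (multiples of 3), products cycled
    through a small annotation vocabulary.
    """
    rng = random.Random(seed)
    features = []
    pos = 1 + rng.randrange(50, 200)
    for i in range(n_cds):
        length = 3 * rng.randrange(mean_length // 9, 5 * mean_length // 9 + 1)
        strand = 1 if rng.random() < 0.6 else -1
        # SimpleLocation is 0-based half-open; pos is 1-based inclusive
        features.append(
            SeqFeature(
                SimpleLocation(pos - 1, pos - 1 + length, strand=strand),
                type="CDS",
                qualifiers={
                    "gene": [f"syn{i:02d}"],
                    "product": [_PRODUCTS[i % len(_PRODUCTS)]],
                },
            )
        )
        pos += length + rng.randrange(20, 400)
    total = pos + rng.randrange(50, 200)
    seq = Seq("".join(rng.choice("ACGT") for _ in range(total)))
    record = SeqRecord(
        seq,
        id="SYNREC01",
        name="SYNREC01",
        description=f"synthetic record with {n_cds} CDS features (seed {seed})",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    record.features = features
    return record
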