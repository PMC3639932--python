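"""Overlay tracks: positioned scored elements, gene-keyed quantitative data,
color gradients, row ranking, and category color schemes.

This module realizes the "data import" side of comparative context maps:
predicted regulatory elements (e.g. transcription-factor binding sites with
similarity scores) are drawn as strand-directed purple arrows above the
gene baseline, and quantitative per-gene data (e.g. log expression ratios
from a microarray experiment) are mapped through a red-yellow-green
gradient — red for down-regulation — into a horizontal bar below the genes.
Rows can then be ranked by either key so predictions and measurements can
be read against each other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

from .context import ContextWindow
from .errors import ContextmapError, ParseError

# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Element:
    """One positioned, scored element (internal 0-based half-open)."""

    accession: str
    start: int
    end: int
    strand: str          # '+', '-' or 'none'
    score: float
    label: str = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"element {self.label or ''}: start must precede end")


@dataclass
class ElementTrack:
    elements: list

    def for_genome(self, accession: str):
        return [e for e in self.elements if e.accession == accession]

    def overlapping(self, accession: str, start: int, end: int):
        return [e for e in self.for_genome(accession)
                if e.start < end and e.end > start]


@dataclass
class QuantTrack:
    """Gene identifier -> real value, e.g. expression log-ratios."""

    values: dict
    transform: str = "symmetric-about-zero"   # or "linear"

    @property
    def value_domain(self):
        vals = list(self.values.values())
        return (min(vals), max(vals)) if vals else (0.0, 0.0)


def read_element_track(path, dialect: str = "tsv") -> ElementTrack:
    """Read positioned elements.

    ``tsv``: columns accession, start, stop, strand, score[, label] with
    1-based inclusive coordinates. ``bed``: standard BED with name in
    column 4 and score in column 5 (already 0-based half-open).
    Elements on genomes that are not loaded are retained; a track may span
    more genomes than the current view.
    """
    if dialect not in ("tsv", "bed"):
        raise ContextmapError(f"unknown element track dialect '{dialect}'")
    elements = []
    for lineno, line in enumerate(open(path).read().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track ", "browser ")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            if dialect == "tsv":
                acc, s, e, strand, score = parts[0], int(parts[1]), int(parts[2]), parts[3], float(parts[4])
                label = parts[5] if len(parts) > 5 else None
                start, end = s - 1, e
            else:
                acc, start, end = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else None
                score = float(parts[4]) if len(parts) > 4 else 0.0
                strand = parts[5] if len(parts) > 5 else "none"
            if strand not in ("+", "-"):
                strand = "none"
            elements.append(Element(accession=acc, start=start, end=end,
                                    strand=strand, score=score, label=label))
        except (IndexError, ValueError) as exc:
            raise ParseError(f"malformed element line: {line!r} ({exc})",
                             line=lineno) from None
    return ElementTrack(elements=elements)


def read_quant_table(path) -> QuantTrack:
    """Read a two-column TSV of (gene id, value). Duplicate IDs are an
    error; non-numeric values are reported with their line number."""
    values = {}
    lines = open(path).read().splitlines()
    start_at = 0
    if lines and not _is_quant_row(lines[0]):
        start_at = 1  # header row
    for lineno, line in enumerate(lines[start_at:], start=start_at + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ParseError(f"expected 'id<TAB>value', got {line!r}", line=lineno)
        key = parts[0]
        try:
            value = float(parts[1])
        except ValueError:
            raise ParseError(f"non-numeric value {parts[1]!r}", line=lineno) from None
        if key in values:
            raise ContextmapError(f"duplicate identifier '{key}' in quant table")
        values[key] = value
    return QuantTrack(values=values)


def _is_quant_row(line: str) -> bool:
    parts = line.split("\t") if "\t" in line else line.split()
    if len(parts) < 2:
        return False
    try:
        float(parts[1])
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

RED = (255, 0, 0)
YELLOW = (255, 255, 0)
GREEN = (0, 200, 0)
NEUTRAL = (200, 200, 200)


@dataclass(frozen=True)
class ColorGradient:
    """Piecewise-linear three-point gradient over (min, mid, max)."""

    domain: tuple                      # (min, mid, max)
    low_color: tuple = RED
    mid_color: tuple = YELLOW
    high_color: tuple = GREEN

    def __post_init__(self):
        lo, mid, hi = self.domain
        if not (lo <= mid <= hi):
            raise ValueError(f"gradient domain {self.domain} is not ordered")

    @property
    def degenerate(self) -> bool:
        return self.domain[0] == self.domain[2]


def gradient_for_track(track: QuantTrack) -> ColorGradient:
    """Gradient matched to a track's value domain.

    For the default symmetric-about-zero transform (log-ratio-like data)
    the midpoint color is anchored at value 0; a linear transform puts it
    at the domain midpoint.
    """
    lo, hi = track.value_domain
    if track.transform == "symmetric-about-zero" and lo < 0.0 < hi:
        mid = 0.0
    else:
        mid = (lo + hi) / 2.0
    return ColorGradient(domain=(lo, mid, hi))


def _lerp(c0, c1, t: float):
    return tuple(int(round(c0[i] + (c1[i] - c0[i]) * t)) for i in range(3))


def value_to_color(gradient: ColorGradient, v: float):
    """Map a value through the gradient; out-of-domain values clamp to the
    endpoint colors, a degenerate domain returns the midpoint color."""
    lo, mid, hi = gradient.domain
    if gradient.degenerate:
        return gradient.mid_color
    if v <= lo:
        return gradient.low_color
    if v >= hi:
        return gradient.high_color
    if v == mid:
        return gradient.mid_color
    if v < mid:
        if mid == lo:
            return gradient.mid_color
        return _lerp(gradient.low_color, gradient.mid_color, (v - lo) / (mid - lo))
    if hi == mid:
        return gradient.mid_color
    return _lerp(gradient.mid_color, gradient.high_color, (v - mid) / (hi - mid))


def hex_color(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


# ---------------------------------------------------------------------------
# Attaching overlays to rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacedElement:
    """An element positioned in a row's display frame (mirrored if flipped)."""

    element: Element
    display_start: float
    display_end: float
    display_strand: str


def attach_overlays(rows, elements: ElementTrack = None,
                    quant: QuantTrack = None,
                    gradient: ColorGradient = None):
    """Attach element and quantitative overlays to context rows, in place.

    Elements overlapping a row's window get display coordinates through the
    row's transform (mirrored with reversed arrow direction when the row is
    flipped). Every member gene with a value in the quant track gets a
    value and a gradient color; genes without values render neutral.
    Returns the rows for chaining.
    """
    if quant is not None and gradient is None:
        gradient = gradient_for_track(quant)
    quant_lower = {}
    if quant is not None:
        quant_lower = {k.lower(): v for k, v in quant.values.items()}
    for row in rows:
        row.placed_elements = []
        row.member_values = {}
        row.member_colors = {}
        if row.is_placeholder:
            continue
        if elements is not None:
            for e in elements.overlapping(row.genome, row.window_start, row.window_end):
                ds, de = row.display_interval(e.start, e.end)
                row.placed_elements.append(PlacedElement(
                    element=e, display_start=ds, display_end=de,
                    display_strand=row.display_strand(e.strand),
                ))
            row.placed_elements.sort(key=lambda p: (p.display_start, p.display_end))
        if quant is not None:
            for member in row.members:
                value = None
                for token in member.all_ids():
                    if token.lower() in quant_lower:
                        value = quant_lower[token.lower()]
                        break
                if value is not None:
                    row.member_values[member.primary_id] = value
                    row.member_colors[member.primary_id] = value_to_color(gradient, value)
    return rows


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def row_rank_key(row: ContextWindow, key: str):
    """The ranking key of one row: the maximum element score, or the anchor
    gene's quantitative value; None when the row carries no key data."""
    if key == "element_score":
        scores = [p.element.score for p in row.placed_elements]
        return max(scores) if scores else None
    if key == "quant_value":
        if row.anchor is None:
            return None
        return row.member_values.get(row.anchor.primary_id)
    raise ContextmapError(f"unknown ranking key '{key}'")


def rank_rows(rows, key: str = "quant_value", direction: str = "ascending"):
    """Stable reorder of rows by their key; keyless rows keep their relative
    order at the end. Always a permutation of the input."""
    if direction not in ("ascending", "descending"):
        raise ContextmapError(f"unknown ranking direction '{direction}'")
    keyed, keyless = [], []
    for i, row in enumerate(rows):
        k = row_rank_key(row, key)
        (keyless if k is None else keyed).append((k, i, row))
    reverse = direction == "descending"
    keyed.sort(key=lambda t: (-t[0] if reverse else t[0], t[1]))
    return [row for _, _, row in keyed] + [row for _, _, row in keyless]


# ---------------------------------------------------------------------------
# Category color schemes
# ---------------------------------------------------------------------------

#: conventional fixed palette for the 26 single-letter COG functional classes
COG_PALETTE = {
    "J": (252, 204, 204), "A": (252, 220, 236), "K": (250, 220, 252),
    "L": (236, 220, 252), "B": (220, 220, 252), "D": (252, 252, 220),
    "Y": (252, 252, 180), "V": (252, 236, 180), "T": (252, 220, 180),
    "M": (236, 252, 220), "N": (220, 252, 220), "Z": (204, 252, 204),
    "W": (204, 252, 220), "U": (204, 252, 236), "O": (204, 252, 252),
    "C": (188, 252, 188), "G": (204, 236, 252), "E": (204, 220, 252),
    "F": (220, 204, 252), "H": (236, 204, 252), "I": (252, 204, 252),
    "P": (252, 204, 236), "Q": (252, 204, 220), "R": (224, 224, 224),
    "S": (200, 200, 200), "X": (180, 180, 180),
}

#: general-purpose qualitative palette for Pfam / location schemes
CATEGORY_PALETTE = [
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
    (57, 59, 121), (82, 84, 163), (107, 110, 207), (156, 158, 222),
    (99, 121, 57), (140, 162, 82), (181, 207, 107), (206, 219, 156),
    (140, 109, 49), (189, 158, 57), (231, 186, 82), (231, 203, 148),
]


def stable_hash(identifier: str) -> int:
    """Deterministic across runs and processes (unlike builtin hash)."""
    return zlib.crc32(identifier.encode("utf-8"))


def assign_category_colors(categories, scheme: str = "pfam"):
    """Deterministic identifier -> RGB assignment for a legend.

    The base slot is ``stable_hash(id) mod palette size`` so an identifier
    keeps its color across figures and genome sets; when two identifiers in
    the same figure collide, the later one (in sorted order, so the result
    is independent of input order) probes forward to the next free slot.
    With more identifiers than slots colors repeat and the legend flags it.
    Returns ``(mapping, repeated_flag)``.
    """
    if scheme == "cog":
        mapping = {}
        for cat in categories:
            letter = (cat or "").upper()[:1]
            mapping[cat] = COG_PALETTE.get(letter, NEUTRAL)
        return mapping, False
    if scheme not in ("pfam", "location"):
        raise ContextmapError(f"unknown color scheme '{scheme}'")
    palette = CATEGORY_PALETTE
    n = len(palette)
    taken = {}
    mapping = {}
    repeated = False
    for cat in sorted(set(categories)):
        slot = stable_hash(cat) % n
        for probe in range(n):
            candidate = (slot + probe) % n
            if candidate not in taken:
                taken[candidate] = cat
                mapping[cat] = palette[candidate]
                break
        else:
            repeated = True
            mapping[cat] = palette[slot]
    return mapping, repeated


def legend_tsv(mapping) -> str:
    """Legend table written alongside every figure: identifier, hex color."""
    lines = ["identifier\tcolor"]
    for key in mapping:
        lines.append(f"{key}\t{hex_color(mapping[key])}")
    return "\n".join(lines) + "\n"
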