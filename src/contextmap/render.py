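"""Deterministic SVG rendering of linear context maps, circular genome maps,
and legends.

The renderer is split in two stages: ``build_scene`` turns context rows
(plus an optional tree layout and overlay attachments) into a
resolution-independent :class:`SceneModel`; ``render_linear_svg`` emits the
scene as SVG text. Identical scenes always render to byte-identical
documents: floats are formatted with a fixed precision, a single generic
sans-serif family is embedded, and nothing depends on dict iteration order
that is not itself deterministic.

Gene glyphs are strand-directed pentagon arrows carrying a machine-readable
``class="gene"`` and ``data-identifier`` attribute plus an embedded
``<title>`` tooltip (identifier, product, COG), so documents remain
scriptable and self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.sax.saxutils import escape

from .errors import CapabilityError, ContextmapError
from .overlays import (NEUTRAL, ColorGradient, assign_category_colors,
                       gradient_for_track, hex_color, value_to_color)

# row geometry (px)
ROW_HEIGHT = 64
ELEMENT_LANE = 14      # purple element arrows above the genes
GENE_LANE = 30
QUANT_LANE = 12        # quantitative bar below the genes
LANE_GAP = 2

PURPLE = (128, 0, 128)
TRNA_GREY = (235, 235, 235)


def fmt(x: float) -> str:
    """Fixed two-decimal float formatting so output is byte-stable."""
    return f"{x:.2f}"


@dataclass
class GeneGlyph:
    identifier: str
    x1: float
    x2: float
    direction: int            # +1 arrow points right, -1 left
    fill: tuple
    label: str
    tooltip: str
    kind: str = "CDS"


@dataclass
class ElementGlyph:
    x1: float
    x2: float
    direction: int            # 0 = no strand (rectangle)
    tooltip: str


@dataclass
class QuantCell:
    x1: float
    x2: float
    fill: tuple
    tooltip: str


@dataclass
class RowScene:
    label: str
    y_top: float
    glyphs: list = field(default_factory=list)
    elements: list = field(default_factory=list)
    quant_cells: list = field(default_factory=list)

    @property
    def y_center(self) -> float:
        return self.y_top + ROW_HEIGHT / 2.0


@dataclass
class TreePanel:
    edges: list               # ((x1,y1),(x2,y2)) in px
    leaf_points: list         # (x, y, label)
    width: float


@dataclass
class SceneModel:
    rows: list
    canvas_width: float
    canvas_height: float
    scale: float
    label_mode: str
    color_mode: str
    tree_panel: TreePanel = None
    legend: dict = field(default_factory=dict)
    legend_repeated: bool = False
    gradient: ColorGradient = None


@dataclass
class MapSettings:
    """Knobs of the comparative map: scale (px per nt), labeling, coloring."""

    scale: float = 0.05
    label_mode: str = "locus_tag"       # trivial_name | locus_tag | alt_id | none
    color_mode: str = "cog"             # cog | pfam | location | gc | plain
    margin: float = 10.0
    label_gutter: float = 120.0
    tree_width: float = 140.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ContextmapError("scale must be positive")
        if self.label_mode not in ("trivial_name", "locus_tag", "alt_id", "none"):
            raise ContextmapError(f"unknown label_mode '{self.label_mode}'")
        if self.color_mode not in ("cog", "pfam", "location", "gc", "plain"):
            raise ContextmapError(f"unknown color_mode '{self.color_mode}'")


def _gene_label(feature, mode: str) -> str:
    if mode == "none":
        return ""
    if mode == "trivial_name":
        return feature.trivial_name or feature.primary_id
    if mode == "alt_id":
        return feature.alt_ids[0] if feature.alt_ids else feature.primary_id
    return feature.primary_id


def _truncate_label(text: str, width_px: float) -> str:
    budget = max(int(width_px / 6.5), 1)   # ~6.5 px per character
    if len(text) <= budget:
        return text
    if budget <= 1:
        return "…"
    half = max((budget - 1) // 2, 1)
    return text[:half] + "…" + text[-half:]


def _category_of(feature, mode: str):
    if mode == "cog":
        return feature.cog_category
    if mode == "pfam":
        return feature.pfam_domains[0][0] if feature.pfam_domains else None
    if mode == "location":
        return feature.location_prediction
    return None


def build_scene(rows, tree_layout=None, settings: MapSettings = None) -> SceneModel:
    """Assemble a :class:`SceneModel` from context rows.

    Gene x-positions are ``(display_position - window_start) * scale``; the
    row's display transform (mirroring for flipped rows) is already folded
    into the display positions, so flipped rows naturally come out with
    reversed glyph order and inverted arrowheads. Quantitative bar cells
    sit beneath their genes, element arrows above.
    """
    settings = settings or MapSettings()
    rows = list(rows)
    if not rows:
        raise ContextmapError("build_scene requires at least one row")
    if tree_layout is not None and len(tree_layout.leaf_order) != len(rows):
        raise ContextmapError(
            f"tree has {len(tree_layout.leaf_order)} leaves but {len(rows)} rows given"
        )

    # color scheme over all displayed genes
    legend, repeated, gradient = {}, False, None
    if settings.color_mode in ("cog", "pfam", "location"):
        cats = []
        for row in rows:
            for m in row.members:
                c = _category_of(m, settings.color_mode)
                if c is not None:
                    cats.append(c)
        legend, repeated = assign_category_colors(cats, scheme=settings.color_mode)
    elif settings.color_mode == "gc":
        gcs = [m.gc_percent for row in rows for m in row.members
               if m.gc_percent is not None]
        if gcs:
            lo, hi = min(gcs), max(gcs)
            gradient = ColorGradient(domain=(lo, (lo + hi) / 2.0, hi))

    tree_x0 = settings.margin
    rows_x0 = settings.margin + settings.label_gutter
    if tree_layout is not None:
        rows_x0 += settings.tree_width + settings.margin

    max_span = max((r.span for r in rows if not r.is_placeholder), default=1)
    canvas_w = rows_x0 + max_span * settings.scale + settings.margin
    canvas_h = 2 * settings.margin + ROW_HEIGHT * len(rows)

    scene_rows = []
    for i, row in enumerate(rows):
        y_top = settings.margin + i * ROW_HEIGHT
        rs = RowScene(label=row.label or "", y_top=y_top)
        if not row.is_placeholder:
            span_px = row.span * settings.scale

            def to_px(d):
                return rows_x0 + (d - row.window_start) * settings.scale

            for m in row.sorted_members():
                d1, d2 = row.display_interval(m.start, m.end)
                x1 = min(max(to_px(d1), rows_x0), rows_x0 + span_px)
                x2 = min(max(to_px(d2), rows_x0), rows_x0 + span_px)
                strand_disp = row.display_strand(m.strand)
                if m.kind != "CDS":
                    fill = TRNA_GREY
                elif settings.color_mode == "gc" and gradient is not None \
                        and m.gc_percent is not None:
                    fill = value_to_color(gradient, m.gc_percent)
                elif settings.color_mode in ("cog", "pfam", "location"):
                    cat = _category_of(m, settings.color_mode)
                    fill = legend.get(cat, NEUTRAL) if cat is not None else NEUTRAL
                else:
                    fill = NEUTRAL
                tooltip_bits = [m.primary_id]
                if m.alt_ids:
                    tooltip_bits.append(",".join(m.alt_ids))
                if m.product:
                    tooltip_bits.append(m.product)
                if m.cog_category:
                    tooltip_bits.append(f"COG:{m.cog_category}")
                rs.glyphs.append(GeneGlyph(
                    identifier=m.primary_id, x1=x1, x2=x2,
                    direction=1 if strand_disp == "+" else -1,
                    fill=fill,
                    label=_truncate_label(_gene_label(m, settings.label_mode), x2 - x1),
                    tooltip=" | ".join(tooltip_bits),
                    kind=m.kind,
                ))
                value = row.member_values.get(m.primary_id)
                rs.quant_cells.append(QuantCell(
                    x1=x1, x2=x2,
                    fill=row.member_colors.get(m.primary_id, NEUTRAL),
                    tooltip=(f"{m.primary_id}: {value:g}" if value is not None
                             else f"{m.primary_id}: no value"),
                ))
            for p in row.placed_elements:
                x1 = min(max(to_px(p.display_start), rows_x0), rows_x0 + span_px)
                x2 = min(max(to_px(p.display_end), rows_x0), rows_x0 + span_px)
                direction = {"+": 1, "-": -1}.get(p.display_strand, 0)
                label = p.element.label or "element"
                rs.elements.append(ElementGlyph(
                    x1=x1, x2=x2, direction=direction,
                    tooltip=f"{label} | score={p.element.score:g}",
                ))
        scene_rows.append(rs)

    panel = None
    if tree_layout is not None:
        xs = tree_layout.max_x or 1.0
        def tx(x):
            return tree_x0 + (x / xs) * settings.tree_width
        def ty(y):
            return settings.margin + y * ROW_HEIGHT + ROW_HEIGHT / 2.0
        edges = [((tx(px), ty(py)), (tx(cx), ty(cy)))
                 for (px, py), (cx, cy) in tree_layout.edges]
        leaf_y = {label: i for i, label in enumerate(tree_layout.leaf_order)}
        leaf_points = [(tree_x0 + settings.tree_width, ty(leaf_y[lbl]), lbl)
                       for lbl in tree_layout.leaf_order]
        panel = TreePanel(edges=edges, leaf_points=leaf_points,
                          width=settings.tree_width)

    scene = SceneModel(
        rows=scene_rows, canvas_width=canvas_w, canvas_height=canvas_h,
        scale=settings.scale, label_mode=settings.label_mode,
        color_mode=settings.color_mode, tree_panel=panel,
        legend=legend, legend_repeated=repeated, gradient=gradient,
    )
    _validate_scene(scene)
    return scene


def _validate_scene(scene: SceneModel):
    for rs in scene.rows:
        for g in rs.glyphs:
            if not (0 <= g.x1 <= scene.canvas_width and 0 <= g.x2 <= scene.canvas_width):
                raise ContextmapError(
                    f"glyph {g.identifier} x-extent [{g.x1},{g.x2}] outside canvas"
                )
    tops = [rs.y_top for rs in scene.rows]
    if tops != sorted(tops) or len(set(tops)) != len(tops):
        raise ContextmapError("row y-bands must be disjoint and ordered")


# ---------------------------------------------------------------------------
# Linear SVG emission
# ---------------------------------------------------------------------------

SVG_HEADER = ('<?xml version="1.0" encoding="UTF-8"?>\n'
              '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
              'width="{w}" height="{h}" viewBox="0 0 {w} {h}">\n'
              '<style>text{{font-family:sans-serif;}}</style>\n')


def _pentagon_points(x1, x2, y_top, height, direction):
    """Strand-directed pentagon arrow; head is a fixed fraction, capped."""
    width = x2 - x1
    head = min(width * 0.35, 8.0)
    y1, y2 = y_top, y_top + height
    ym = y_top + height / 2.0
    if direction >= 0:
        pts = [(x1, y1), (x2 - head, y1), (x2, ym), (x2 - head, y2), (x1, y2)]
    else:
        pts = [(x2, y1), (x1 + head, y1), (x1, ym), (x1 + head, y2), (x2, y2)]
    return " ".join(f"{fmt(x)},{fmt(y)}" for x, y in pts)


def render_linear_svg(scene: SceneModel) -> str:
    """Emit a linear comparative context map as SVG 1.1 text."""
    out = [SVG_HEADER.format(w=fmt(scene.canvas_width), h=fmt(scene.canvas_height))]
    if scene.tree_panel is not None:
        out.append('<g class="tree" stroke="#444444" fill="none">\n')
        for (x1, y1), (x2, y2) in scene.tree_panel.edges:
            # rectangular tree edges: vertical from parent, then horizontal
            out.append(f'<path d="M {fmt(x1)} {fmt(y1)} V {fmt(y2)} H {fmt(x2)}"/>\n')
        out.append('</g>\n')
    for rs in scene.rows:
        out.append(f'<g class="row" data-label="{escape(rs.label, {chr(34): "&quot;"})}">\n')
        label_y = rs.y_top + ELEMENT_LANE + LANE_GAP + GENE_LANE / 2.0 + 3
        out.append(f'<text class="row-label" x="4.00" y="{fmt(label_y)}" '
                   f'font-size="10">{escape(rs.label)}</text>\n')
        gene_y = rs.y_top + ELEMENT_LANE + LANE_GAP
        for g in rs.glyphs:
            pts = _pentagon_points(g.x1, g.x2, gene_y, GENE_LANE, g.direction)
            out.append(f'<polygon class="gene" data-identifier="{escape(g.identifier, {chr(34): "&quot;"})}" '
                       f'points="{pts}" fill="{hex_color(g.fill)}" stroke="#333333" '
                       f'stroke-width="0.5"><title>{escape(g.tooltip)}</title></polygon>\n')
            if g.label:
                cx = (g.x1 + g.x2) / 2.0
                cy = gene_y + GENE_LANE / 2.0 + 3
                out.append(f'<text class="gene-label" x="{fmt(cx)}" y="{fmt(cy)}" '
                           f'font-size="9" text-anchor="middle">{escape(g.label)}</text>\n')
        quant_y = gene_y + GENE_LANE + LANE_GAP
        for c in rs.quant_cells:
            out.append(f'<rect class="quant" x="{fmt(c.x1)}" y="{fmt(quant_y)}" '
                       f'width="{fmt(c.x2 - c.x1)}" height="{fmt(QUANT_LANE - 2)}" '
                       f'fill="{hex_color(c.fill)}"><title>{escape(c.tooltip)}</title></rect>\n')
        elem_y = rs.y_top + 2
        for e in rs.elements:
            if e.direction == 0:
                out.append(f'<rect class="element" x="{fmt(e.x1)}" y="{fmt(elem_y)}" '
                           f'width="{fmt(e.x2 - e.x1)}" height="{fmt(ELEMENT_LANE - 4)}" '
                           f'fill="{hex_color(PURPLE)}"><title>{escape(e.tooltip)}</title></rect>\n')
            else:
                pts = _pentagon_points(e.x1, e.x2, elem_y, ELEMENT_LANE - 4, e.direction)
                out.append(f'<polygon class="element" points="{pts}" '
                           f'fill="{hex_color(PURPLE)}"><title>{escape(e.tooltip)}</title></polygon>\n')
        out.append('</g>\n')
    out.append('</svg>\n')
    return "".join(out)


# ---------------------------------------------------------------------------
# Circular genome maps
# ---------------------------------------------------------------------------

PLUS_COLOR = (70, 100, 220)      # plus-strand ORFs: blue
MINUS_COLOR = (150, 150, 150)    # minus-strand ORFs: grey
HIGHLIGHT_COLOR = (0, 160, 60)   # highlighted genes: green
GC_COLOR = (210, 40, 40)         # GC% profile: red
DOT_COLOR = (0, 160, 60)         # element dots: green


def position_angle(position: float, genome_length: int) -> float:
    """Angle in degrees of a genomic position: 360 * p / L, 0 at 12 o'clock,
    increasing clockwise."""
    return 360.0 * (position % genome_length) / genome_length


def _polar(cx, cy, radius, angle_deg):
    rad = math.radians(angle_deg)
    return cx + radius * math.sin(rad), cy - radius * math.cos(rad)


@dataclass
class ArcSpec:
    identifier: str
    angle_start: float
    angle_end: float
    r_inner: float
    r_outer: float
    fill: tuple
    tooltip: str


@dataclass
class CircularSceneModel:
    genome_length: int
    size: float
    arcs: list = field(default_factory=list)       # strand tracks + highlights
    gc_points: list = field(default_factory=list)  # (angle, radius)
    dots: list = field(default_factory=list)       # (angle, tooltip)
    dot_radius_track: float = 0.0
    title: str = ""


def build_circular_scene(genome, highlight_ids=(), elements=None,
                         gc_window: int = 2000, gc_step: int = 1000,
                         size: float = 640.0) -> CircularSceneModel:
    """Circular genome map: plus-strand ORFs (blue, outer ring), minus-strand
    ORFs (grey), highlight marks (green), a windowed GC% profile (red) and
    element dots (green), with position 0 at 12 o'clock."""
    if genome.length <= 0:
        raise ContextmapError("circular map requires a positive genome length")
    L = genome.length
    scene = CircularSceneModel(genome_length=L, size=size, title=genome.accession)
    r_plus = (0.40 * size, 0.45 * size)
    r_minus = (0.34 * size, 0.39 * size)
    r_high = (0.46 * size, 0.49 * size)
    scene.dot_radius_track = 0.31 * size
    highlights = {h.lower() for h in highlight_ids}
    for f in genome.features:
        a1, a2 = position_angle(f.start, L), 360.0 * f.end / L
        band = r_plus if f.strand == "+" else r_minus
        color = PLUS_COLOR if f.strand == "+" else MINUS_COLOR
        scene.arcs.append(ArcSpec(
            identifier=f.primary_id, angle_start=a1, angle_end=a2,
            r_inner=band[0], r_outer=band[1], fill=color,
            tooltip=f"{f.primary_id}" + (f" | {f.product}" if f.product else ""),
        ))
        if {t.lower() for t in f.all_ids()} & highlights:
            scene.arcs.append(ArcSpec(
                identifier=f"highlight:{f.primary_id}",
                angle_start=a1, angle_end=a2,
                r_inner=r_high[0], r_outer=r_high[1], fill=HIGHLIGHT_COLOR,
                tooltip=f"highlight | {f.primary_id}",
            ))
    if genome.has_sequence and gc_window > 0:
        base, amp = 0.24 * size, 0.06 * size
        values = []
        for p in range(0, L, gc_step):
            chunk = genome.slice(p, p + gc_window) if genome.topology == "circular" \
                else genome.sequence[p:min(p + gc_window, L)]
            chunk = chunk.upper()
            gc = chunk.count("G") + chunk.count("C")
            at = chunk.count("A") + chunk.count("T")
            values.append((p, 100.0 * gc / (gc + at) if gc + at else 50.0))
        lo = min(v for _, v in values)
        hi = max(v for _, v in values)
        span = (hi - lo) or 1.0
        for p, v in values:
            scene.gc_points.append(
                (position_angle(p, L), base + amp * (v - lo) / span))
    if elements is not None:
        for e in elements.for_genome(genome.accession):
            mid = (e.start + e.end) / 2.0
            scene.dots.append((position_angle(mid, L),
                               f"{e.label or 'element'} | score={e.score:g}"))
    return scene


def render_circular_svg(scene: CircularSceneModel) -> str:
    """Emit a circular genome map as SVG 1.1 text."""
    s = scene.size
    cx = cy = s / 2.0
    out = [SVG_HEADER.format(w=fmt(s), h=fmt(s))]
    out.append(f'<text x="{fmt(cx)}" y="{fmt(cy)}" text-anchor="middle" '
               f'font-size="14">{escape(scene.title)}</text>\n')
    out.append('<g class="arcs">\n')
    for arc in scene.arcs:
        out.append(_arc_path(cx, cy, arc))
    out.append('</g>\n')
    if scene.gc_points:
        pts = " ".join(f"{fmt(x)},{fmt(y)}"
                       for x, y in (_polar(cx, cy, r, a) for a, r in scene.gc_points))
        out.append(f'<polygon class="gc-profile" points="{pts}" fill="none" '
                   f'stroke="{hex_color(GC_COLOR)}" stroke-width="1"/>\n')
    for angle, tooltip in scene.dots:
        x, y = _polar(cx, cy, scene.dot_radius_track, angle)
        out.append(f'<circle class="element-dot" cx="{fmt(x)}" cy="{fmt(y)}" r="3.00" '
                   f'fill="{hex_color(DOT_COLOR)}"><title>{escape(tooltip)}</title></circle>\n')
    out.append('</svg>\n')
    return "".join(out)


def _arc_path(cx, cy, arc: ArcSpec) -> str:
    a1, a2 = arc.angle_start, arc.angle_end
    if a2 <= a1:
        a2 += 360.0
    large = 1 if (a2 - a1) > 180.0 else 0
    x1o, y1o = _polar(cx, cy, arc.r_outer, a1)
    x2o, y2o = _polar(cx, cy, arc.r_outer, a2)
    x2i, y2i = _polar(cx, cy, arc.r_inner, a2)
    x1i, y1i = _polar(cx, cy, arc.r_inner, a1)
    ro, ri = fmt(arc.r_outer), fmt(arc.r_inner)
    d = (f"M {fmt(x1o)} {fmt(y1o)} "
         f"A {ro} {ro} 0 {large} 1 {fmt(x2o)} {fmt(y2o)} "
         f"L {fmt(x2i)} {fmt(y2i)} "
         f"A {ri} {ri} 0 {large} 0 {fmt(x1i)} {fmt(y1i)} Z")
    cls = "highlight" if arc.identifier.startswith("highlight:") else "orf"
    data_id = arc.identifier.split("highlight:", 1)[-1]
    return (f'<path class="{cls}" data-identifier="{escape(data_id, {chr(34): "&quot;"})}" '
            f'd="{d}" fill="{hex_color(arc.fill)}">'
            f'<title>{escape(arc.tooltip)}</title></path>\n')


# ---------------------------------------------------------------------------
# Legends and raster export
# ---------------------------------------------------------------------------


def render_legend(color_assignments=None, gradient: ColorGradient = None) -> str:
    """One swatch + label per category; a tick-labelled gradient bar when a
    gradient is supplied."""
    color_assignments = color_assignments or {}
    if not color_assignments and gradient is None:
        raise ContextmapError("render_legend needs assignments or a gradient")
    rows = len(color_assignments)
    height = 10 + rows * 18 + (60 if gradient is not None else 0) + 10
    out = [SVG_HEADER.format(w="260.00", h=fmt(height))]
    y = 10.0
    for key in color_assignments:
        out.append(f'<rect class="swatch" x="10.00" y="{fmt(y)}" width="14.00" '
                   f'height="14.00" fill="{hex_color(color_assignments[key])}" '
                   f'stroke="#333333"/>\n')
        out.append(f'<text x="30.00" y="{fmt(y + 11)}" font-size="11">'
                   f'{escape(str(key))}</text>\n')
        y += 18.0
    if gradient is not None:
        lo, mid, hi = gradient.domain
        y += 8.0
        # 3-stop gradient bar drawn as two linearGradient halves
        out.append('<defs>\n')
        out.append(f'<linearGradient id="grad-lo"><stop offset="0" stop-color="{hex_color(gradient.low_color)}"/>'
                   f'<stop offset="1" stop-color="{hex_color(gradient.mid_color)}"/></linearGradient>\n')
        out.append(f'<linearGradient id="grad-hi"><stop offset="0" stop-color="{hex_color(gradient.mid_color)}"/>'
                   f'<stop offset="1" stop-color="{hex_color(gradient.high_color)}"/></linearGradient>\n')
        out.append('</defs>\n')
        out.append(f'<rect class="gradient-bar" x="10.00" y="{fmt(y)}" width="100.00" '
                   f'height="12.00" fill="url(#grad-lo)"/>\n')
        out.append(f'<rect class="gradient-bar" x="110.00" y="{fmt(y)}" width="100.00" '
                   f'height="12.00" fill="url(#grad-hi)"/>\n')
        for tx, tv in ((10.0, lo), (110.0, mid), (210.0, hi)):
            out.append(f'<text class="tick" x="{fmt(tx)}" y="{fmt(y + 26)}" '
                       f'font-size="10" text-anchor="middle">{tv:g}</text>\n')
    out.append('</svg>\n')
    return "".join(out)


def export_raster(svg_text: str, format: str, path) -> None:
    """Convert SVG text to PNG or PDF via the optional cairosvg backend.

    Raster export is an optional capability: when no backend is installed
    the operation fails with a clear SVG-only message instead of crashing.
    """
    if format not in ("png", "pdf"):
        raise ContextmapError(f"unknown raster format '{format}'")
    try:
        import cairosvg
    except ImportError:
        raise CapabilityError(
            "raster export needs the 'cairosvg' backend, which is not "
            "installed; output remains SVG-only"
        ) from None
    try:
        if format == "png":
            cairosvg.svg2png(bytestring=svg_text.encode("utf-8"), write_to=str(path))
        else:
            cairosvg.svg2pdf(bytestring=svg_text.encode("utf-8"), write_to=str(path))
    except Exception as exc:
        raise ContextmapError(f"rasterization failed: {exc}") from exc
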