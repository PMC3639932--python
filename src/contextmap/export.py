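"""Bulk gene-linked data export: upstream regions, protein sequences, and
annotation tables for a selected gene set.

Selections are programmatic (explicit identifier lists, the anchors of the
current rows, or all row members); exports run fine without ever building
a map. FASTA headers are pipe-delimited ``id|key=value`` pairs; exported
coordinates are 1-based inclusive so they round-trip through the region
parser.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field

from .context import extract_upstream, get_protein_sequence
from .errors import ContextmapError, TranslationError
from .genome_io import format_pfam_field

PROVENANCE_MODES = ("explicit_ids", "row_anchors", "all_row_members")


@dataclass
class GeneSelection:
    """An ordered gene set with a record of how it was selected."""

    items: list                       # (genome accession, GeneFeature)
    provenance: str = "explicit_ids"

    def __post_init__(self):
        if self.provenance not in PROVENANCE_MODES:
            raise ContextmapError(f"unknown provenance '{self.provenance}'")

    def __len__(self):
        return len(self.items)


def selection_from_rows(rows, mode: str = "row_anchors") -> GeneSelection:
    """Build a selection from context rows: their anchors, or every member."""
    items = []
    for row in rows:
        if row.is_placeholder:
            continue
        if mode == "row_anchors":
            if row.anchor is not None:
                items.append((row.genome, row.anchor))
        elif mode == "all_row_members":
            for m in row.sorted_members():
                items.append((row.genome, m))
        else:
            raise ContextmapError(f"unknown row-selection mode '{mode}'")
    return GeneSelection(items=items, provenance=mode)


def _wrap(seq: str) -> str:
    return "\n".join(textwrap.wrap(seq, 70)) if seq else ""


@dataclass
class ExportReport:
    omitted: list = field(default_factory=list)   # (primary_id, reason)


def export_upstream_fasta(selection: GeneSelection, genomes, length_nt: int,
                          truncate_at_neighbor: bool = True):
    """FASTA of upstream regions in selection order.

    Headers carry the genome, the 1-based inclusive genomic interval, the
    strand and the truncation flag. Zero-length regions (upstream fully
    occupied by a neighbor) are omitted and reported — motif finders
    reject empty sequences.
    Returns ``(fasta_text, report)``.
    """
    if not selection.items:
        raise ContextmapError("export_upstream_fasta: empty selection")
    by_acc = {g.accession: g for g in genomes}
    records = []
    report = ExportReport()
    for accession, gene in selection.items:
        genome = by_acc[accession]
        region = extract_upstream(genome, gene, length_nt, truncate_at_neighbor)
        if not region.sequence:
            report.omitted.append((gene.primary_id, "zero-length upstream region"))
            continue
        a, b = region.genomic_interval
        header = (f">{gene.primary_id}|genome={accession}|region={a + 1}..{b}"
                  f"|strand={gene.strand}|truncated={str(region.truncated).lower()}")
        records.append(header + "\n" + _wrap(region.sequence))
    return "\n".join(records) + ("\n" if records else ""), report


def export_protein_fasta(selection: GeneSelection, genomes):
    """FASTA of protein sequences in selection order; per-gene translation
    failures are collected in the report while successful records are
    still emitted. Returns ``(fasta_text, report)``."""
    if not selection.items:
        raise ContextmapError("export_protein_fasta: empty selection")
    by_acc = {g.accession: g for g in genomes}
    records = []
    report = ExportReport()
    for accession, gene in selection.items:
        try:
            protein = get_protein_sequence(gene, by_acc.get(accession))
        except (TranslationError, ContextmapError) as exc:
            report.omitted.append((gene.primary_id, str(exc)))
            continue
        product = f"|product={gene.product}" if gene.product else ""
        records.append(f">{gene.primary_id}{product}\n" + _wrap(protein))
    return "\n".join(records) + ("\n" if records else ""), report


ANNOTATION_FIELDS = (
    "primary_id", "alt_ids", "trivial_name", "product", "length_nt",
    "protein_length", "cog", "pfam", "location", "gc", "genome",
    "start", "end", "strand", "uniprot",
)


def _field_value(field_name, accession, gene):
    if field_name == "primary_id":
        return gene.primary_id
    if field_name == "alt_ids":
        return ";".join(gene.alt_ids)
    if field_name == "trivial_name":
        return gene.trivial_name or ""
    if field_name == "product":
        return gene.product or ""
    if field_name == "length_nt":
        return str(gene.end - gene.start)
    if field_name == "protein_length":
        return str(len(gene.translation)) if gene.translation else ""
    if field_name == "cog":
        return gene.cog_category or ""
    if field_name == "pfam":
        return format_pfam_field(gene.pfam_domains)
    if field_name == "location":
        return gene.location_prediction or ""
    if field_name == "gc":
        return f"{gene.gc_percent:.2f}" if gene.gc_percent is not None else ""
    if field_name == "genome":
        return accession
    if field_name == "start":
        return str(gene.start + 1)        # 1-based inclusive on output
    if field_name == "end":
        return str(gene.end)
    if field_name == "strand":
        return gene.strand
    if field_name == "uniprot":
        for alt in gene.alt_ids:
            # Uniprot accessions look like P12345 / Q9XyZ1 / A0A0...
            if len(alt) in (6, 10) and alt[0].isalpha() and any(c.isdigit() for c in alt):
                return alt
        return ""
    raise ContextmapError(
        f"unknown export field '{field_name}'; valid fields: {ANNOTATION_FIELDS}"
    )


def export_annotation_tsv(selection: GeneSelection, fields) -> str:
    """Annotation table: one header row naming the requested fields, one row
    per gene in selection order; missing values are empty cells; pfam and
    alt_ids are ';'-joined."""
    fields = list(fields)
    if not fields:
        raise ContextmapError("export_annotation_tsv: fields must be non-empty")
    for f in fields:
        if f not in ANNOTATION_FIELDS:
            raise ContextmapError(
                f"unknown export field '{f}'; valid fields: {ANNOTATION_FIELDS}"
            )
    lines = ["\t".join(fields)]
    for accession, gene in selection.items:
        lines.append("\t".join(_field_value(f, accession, gene) for f in fields))
    return "\n".join(lines) + "\n"
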