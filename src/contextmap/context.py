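"""Context windows, orientation normalization, GC%, upstream and protein sequences.

A *context window* is an anchor gene plus every feature overlapping a
symmetric nucleotide range around it. Windows can be mirrored for display
("identical orientation" of anchors) without ever touching genomic
coordinates: flipping is purely a display transform recorded on the row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import ContextmapError, TranslationError
from .genome_io import GeneFeature, GenomeRecord, RegionQuery

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ContextWindow:
    """An anchor gene and the genes overlapping a window around it.

    ``members`` hold untouched genomic coordinates; when ``flipped`` the
    row is rendered mirrored about the window midline so the anchor reads
    left-to-right. ``display_position`` maps genomic x to display x.
    """

    genome: str
    anchor: GeneFeature
    range_nt: int
    window_start: int
    window_end: int
    members: list
    flipped: bool = False
    label: str = None
    # overlay attachments, populated by overlays.attach_overlays
    placed_elements: list = field(default_factory=list)
    member_values: dict = field(default_factory=dict)
    member_colors: dict = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.window_end - self.window_start

    @property
    def is_placeholder(self) -> bool:
        return self.anchor is None and not self.members

    def display_position(self, x: float) -> float:
        """Map a genomic coordinate into the row's display frame."""
        if self.flipped:
            return (self.window_start + self.window_end) - x
        return x

    def display_interval(self, start: float, end: float):
        a, b = self.display_position(start), self.display_position(end)
        return (b, a) if self.flipped else (a, b)

    def display_strand(self, strand: str) -> str:
        if strand not in ("+", "-"):
            return strand
        if not self.flipped:
            return strand
        return "-" if strand == "+" else "+"

    def sorted_members(self):
        """Members in display order (left to right as drawn)."""
        return sorted(self.members,
                      key=lambda f: self.display_interval(f.start, f.end)[0])


def placeholder_window(label: str = None) -> ContextWindow:
    """An empty row that keeps tree and row stacks aligned for unbound leaves."""
    return ContextWindow(genome=None, anchor=None, range_nt=0,
                         window_start=0, window_end=1, members=[], label=label)


@dataclass
class UpstreamRegion:
    """Sequence 5' of a gene's start codon, in the gene's reading orientation."""

    gene: GeneFeature
    requested_length: int
    sequence: str
    genomic_interval: tuple
    truncated: bool = False
    truncation_cause: str = None


def _overlapping_members(genome: GenomeRecord, start: int, end: int):
    return [f for f in genome.features if f.start < end and f.end > start]


def extract_context(genome: GenomeRecord, anchor: GeneFeature,
                    range_nt: int) -> ContextWindow:
    """Build the context window of ``range_nt`` nucleotides around an anchor.

    The window spans ``[anchor.start - range_nt, anchor.end + range_nt)``
    clamped to the genome; members are all features overlapping it by >= 1 nt.
    """
    if range_nt < 0:
        raise ContextmapError("range_nt must be >= 0")
    if anchor not in genome.features:
        raise ContextmapError(
            f"anchor {anchor.primary_id} does not belong to genome {genome.accession}"
        )
    ws = max(0, anchor.start - range_nt)
    we = min(genome.length, anchor.end + range_nt)
    return ContextWindow(
        genome=genome.accession, anchor=anchor, range_nt=range_nt,
        window_start=ws, window_end=we,
        members=_overlapping_members(genome, ws, we),
        label=anchor.primary_id,
    )


def extract_context_for_region(genome: GenomeRecord,
                               region: RegionQuery) -> ContextWindow:
    """Window over a user region; the anchor is the member whose midpoint is
    nearest the region midpoint (ties -> leftmost). A region covering no genes
    yields an anchorless, renderable row."""
    if region.accession != genome.accession:
        raise ContextmapError(
            f"region accession {region.accession} does not match genome "
            f"{genome.accession}"
        )
    ws, we = max(0, region.start), min(genome.length, region.end)
    if ws >= we:
        raise ContextmapError(
            f"region {region.accession}:{region.start + 1}-{region.end} is empty "
            "after clamping to the genome"
        )
    members = _overlapping_members(genome, ws, we)
    anchor = None
    if members:
        mid = (ws + we) / 2.0
        anchor = min(members, key=lambda f: (abs(f.midpoint - mid), f.start))
    return ContextWindow(
        genome=genome.accession, anchor=anchor, range_nt=0,
        window_start=ws, window_end=we, members=members,
        label=anchor.primary_id if anchor else f"{genome.accession}:{ws + 1}-{we}",
    )


def normalize_orientation(window: ContextWindow) -> ContextWindow:
    """Mirror a row whose anchor is on the minus strand so it reads left-to-right.

    Plus-strand (or anchorless, or already-flipped) rows are returned
    unchanged; genomic coordinates are never altered. Idempotent.
    """
    if window.anchor is None or window.anchor.strand == "+" or window.flipped:
        return window
    return replace(window, flipped=True)


def compute_gene_gc(genome: GenomeRecord, gene: GeneFeature) -> float:
    """GC% of the gene's genomic slice; ambiguity codes are excluded from both
    numerator and denominator. Returns None for an all-ambiguous slice and
    stores the result on the feature."""
    piece = genome.slice(gene.start, gene.end).upper()
    gc = piece.count("G") + piece.count("C")
    at = piece.count("A") + piece.count("T")
    if gc + at == 0:
        gene.gc_percent = None
        return None
    value = 100.0 * gc / (gc + at)
    gene.gc_percent = value
    return value


def _upstream_interval(genome, gene, length_nt):
    """Raw upstream interval before truncation, possibly out of [0, L) for
    circular genomes (wrap handled by GenomeRecord.slice)."""
    if gene.strand == "+":
        return gene.start - length_nt, gene.start
    return gene.end, gene.end + length_nt


def extract_upstream(genome: GenomeRecord, gene: GeneFeature, length_nt: int,
                     truncate_at_neighbor: bool = True) -> UpstreamRegion:
    """Extract the region 5' of a gene's start codon.

    For strand '+' this is ``[start - L, start)``; for strand '-' it is
    ``[end, end + L)`` reverse-complemented so the returned sequence always
    reads 5'->3' toward the start codon. ``truncate_at_neighbor`` shortens
    the region at the nearest intruding feature boundary (any strand);
    linear genome ends always truncate, circular genomes wrap instead.
    """
    if length_nt < 0:
        raise ContextmapError("length_nt must be >= 0")
    genome.require_sequence()
    a, b = _upstream_interval(genome, gene, length_nt)
    truncated = False
    cause = None

    if genome.topology == "linear":
        if a < 0:
            a, truncated, cause = 0, True, "genome-start"
        if b > genome.length:
            b, truncated, cause = genome.length, True, "genome-end"

    if truncate_at_neighbor and b > a:
        # examine neighbors in the (possibly wrapped) interval; shift copies
        # of each feature by -L, 0, +L so circular wrap needs no special case
        shifts = (0,) if genome.topology == "linear" else (-genome.length, 0, genome.length)
        if gene.strand == "+":
            limit = a
            for f in genome.features:
                for sh in shifts:
                    if f is gene and sh == 0:
                        continue  # wrapped copies of the gene itself still truncate
                    fs, fe = f.start + sh, f.end + sh
                    cut = min(fe, gene.start)  # neighbor may overrun the start
                    if fs < b and fe > a and cut > limit:
                        limit, truncated, cause = cut, True, f.primary_id
            a = limit
        else:
            limit = b
            for f in genome.features:
                for sh in shifts:
                    if f is gene and sh == 0:
                        continue
                    fs, fe = f.start + sh, f.end + sh
                    cut = max(fs, gene.end)
                    if fs < b and fe > a and cut < limit:
                        limit, truncated, cause = cut, True, f.primary_id
            b = limit

    seq = genome.slice(a, b) if b > a else ""
    if gene.strand == "-":
        seq = revcomp(seq)
    return UpstreamRegion(
        gene=gene, requested_length=length_nt, sequence=seq,
        genomic_interval=(a, b), truncated=truncated, truncation_cause=cause,
    )


_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]


def get_protein_sequence(gene: GeneFeature, genome: GenomeRecord = None) -> str:
    """Stored translation if present, else on-the-fly translation of the
    coding slice with the bacterial code (alternative starts read as M).

    An internal stop codon raises, signalling a pseudo-gene or a coordinate
    fault rather than silently emitting a '*'-bearing protein.
    """
    if gene.translation:
        return gene.translation
    if genome is None:
        raise ContextmapError(
            f"{gene.primary_id}: no stored translation and no genome supplied"
        )
    genome.require_sequence()
    coding = genome.slice(gene.start, gene.end)
    if gene.strand == "-":
        coding = revcomp(coding)
    if len(coding) % 3:
        raise TranslationError(
            f"{gene.primary_id}: coding length {len(coding)} is not a multiple of 3"
        )
    try:
        protein = str(Seq(coding).translate(table=11, cds=True))
    except Exception:
        # fall back to plain translation to report *where* it went wrong
        plain = str(Seq(coding).translate(table=11))
        body = plain[:-1] if plain.endswith("*") else plain
        if "*" in body:
            raise TranslationError(
                f"{gene.primary_id}: internal stop codon at protein position "
                f"{body.index('*') + 1}"
            ) from None
        raise TranslationError(
            f"{gene.primary_id}: coding slice is not a valid CDS"
        ) from None
    return protein
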