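"""Genome annotation input and query resolution.

Reads bacterial genome annotation from GenBank flat files or GFF3 (+FASTA),
normalizes everything to an internal coordinate convention, and resolves
user queries — identifier lists, product text searches, and tab-separated
region triples — to gene features.

Coordinate convention
---------------------
Internally every interval is 0-based half-open on the forward strand.
All user-facing input and output (GenBank, GFF3, region triples, exported
tables) is 1-based inclusive, converted exactly at the boundary:
``internal_start = user_start - 1``, ``internal_end = user_end``.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import CapabilityError, ContextmapError, ParseError

log = logging.getLogger(__name__)

#: feature kinds retained from annotation files; everything else is dropped
RETAINED_KINDS = ("CDS", "tRNA", "rRNA", "ncRNA", "tmRNA")


@dataclass
class GeneFeature:
    """One annotated gene.

    ``start``/``end`` are 0-based half-open on the forward strand;
    ``strand`` is ``'+'`` or ``'-'``. ``pfam_domains`` are
    ``(accession, within-protein start, within-protein end)`` triples.
    """

    primary_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    alt_ids: tuple = ()
    trivial_name: str = None
    product: str = None
    cog_category: str = None
    pfam_domains: tuple = ()
    location_prediction: str = None
    gc_percent: float = None
    translation: str = None
    compound_collapsed: bool = False
    wraps_origin: bool = False

    def __post_init__(self):
        if not self.primary_id:
            raise ValueError("GeneFeature requires a non-empty primary_id")
        if self.start >= self.end and not self.wraps_origin:
            raise ValueError(
                f"{self.primary_id}: start ({self.start}) must precede end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.primary_id}: strand must be '+' or '-'")
        if self.gc_percent is not None and not (0.0 <= self.gc_percent <= 100.0):
            raise ValueError(f"{self.primary_id}: gc_percent outside [0,100]")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def all_ids(self):
        yield self.primary_id
        yield from self.alt_ids


@dataclass
class GenomeRecord:
    """One genome: an accession, optional sequence, and start-sorted features."""

    accession: str
    length: int
    features: list
    sequence: str = None
    topology: str = "linear"

    def __post_init__(self):
        if not self.accession:
            raise ValueError("GenomeRecord requires a non-empty accession")
        if self.length <= 0:
            raise ValueError(f"{self.accession}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.accession}: sequence length {len(self.sequence)} != "
                f"declared length {self.length}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.accession}: topology must be linear or circular")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None

    def require_sequence(self):
        if not self.has_sequence:
            raise CapabilityError(
                f"genome {self.accession} was loaded without sequence; "
                "GC and sequence-extraction operations are unavailable"
            )

    def slice(self, start: int, end: int) -> str:
        """Forward-strand slice, wrapping across the origin for circular genomes."""
        self.require_sequence()
        if 0 <= start <= end <= self.length:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(
                f"slice [{start},{end}) outside linear genome {self.accession}"
            )
        start %= self.length
        span = end - start if end >= start else end % self.length + self.length - start
        doubled = self.sequence + self.sequence
        return doubled[start : start + span]


@dataclass
class RegionQuery:
    """A user region: internally 0-based half-open (input was 1-based inclusive)."""

    accession: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("RegionQuery start must not exceed end")


@dataclass
class ResolutionReport:
    """Outcome bookkeeping for identifier resolution / table application."""

    unresolved: list = field(default_factory=list)
    ambiguous: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unresolved and not self.ambiguous


# ---------------------------------------------------------------------------
# GenBank / GFF3 readers
# ---------------------------------------------------------------------------

_GFF_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C"}


def _gff_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


def _feature_from_seqfeature(sf, counters) -> GeneFeature:
    quals = sf.qualifiers
    primary = (quals.get("locus_tag") or quals.get("ID") or [None])[0]
    if primary is None:
        counters["skipped"] += 1
        return None
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    start, end = int(parts[0].start), int(parts[-1].end)
    compound = len(parts) > 1
    if compound:
        counters["collapsed"] += 1
    alt = []
    for pid in quals.get("protein_id", []):
        alt.append(pid)
    for xref in quals.get("db_xref", []):
        alt.append(xref.split(":", 1)[-1])
    pfam = _parse_pfam_field((quals.get("pfam_domains") or [None])[0])
    return GeneFeature(
        primary_id=primary,
        start=start,
        end=end,
        strand="-" if sf.location.strand == -1 else "+",
        kind=sf.type,
        alt_ids=tuple(alt),
        trivial_name=(quals.get("gene") or [None])[0],
        product=(quals.get("product") or [None])[0],
        cog_category=(quals.get("cog_category") or [None])[0],
        pfam_domains=pfam,
        location_prediction=(quals.get("sub_location") or [None])[0],
        translation=(quals.get("translation") or [None])[0],
        compound_collapsed=compound,
    )


def _parse_pfam_field(text):
    """Parse 'PF00001:1-120;PF00002:130-200' into domain triples."""
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" in chunk:
            acc, span = chunk.split(":", 1)
            lo, hi = span.split("-", 1)
            out.append((acc, int(lo), int(hi)))
        else:
            out.append((chunk, 0, 0))
    return tuple(out)


def format_pfam_field(domains) -> str:
    return ";".join(f"{acc}:{lo}-{hi}" for acc, lo, hi in domains)


def read_genbank(path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    GenBank 1-based inclusive coordinates become internal 0-based half-open;
    ``complement(...)`` sets strand '-'; compound ``join(...)`` locations are
    collapsed to their outer envelope with ``compound_collapsed=True``.
    A record without an ORIGIN section yields ``sequence=None`` and disables
    sequence-dependent operations.
    """
    record = SeqIO.read(str(path), "genbank")
    counters = {"read": 0, "skipped": 0, "collapsed": 0}
    features = []
    for sf in record.features:
        if sf.type not in RETAINED_KINDS:
            continue
        gf = _feature_from_seqfeature(sf, counters)
        if gf is not None:
            features.append(gf)
            counters["read"] += 1
    try:
        sequence = str(record.seq)
        if not sequence:
            sequence = None
    except Exception:  # Biopython raises on undefined sequence content
        sequence = None
    length = len(sequence) if sequence else len(record.seq)
    topology = record.annotations.get("topology", "linear")
    log.info(
        "read_genbank %s: %d features, %d skipped, %d collapsed",
        record.id, counters["read"], counters["skipped"], counters["collapsed"],
    )
    return GenomeRecord(
        accession=record.id,
        length=length,
        features=features,
        sequence=sequence,
        topology=topology if topology in ("linear", "circular") else "linear",
    )


def read_gff3_with_fasta(gff_path, fasta_path=None):
    """Read a GFF3 file (with embedded ``##FASTA`` or a separate FASTA).

    Returns ``(GenomeRecord, skip_count)``; CDS lines without an ``ID`` or
    ``locus_tag`` attribute are skipped with a warning. A seqid mismatch
    between the GFF3 and the FASTA raises naming both identifiers.
    """
    text = open(gff_path).read()
    fasta_text = None
    if "##FASTA" in text:
        gff_part, fasta_text = text.split("##FASTA", 1)
    else:
        gff_part = text
        if fasta_path is not None:
            fasta_text = open(fasta_path).read()

    db = gffutils.create_db(
        gff_part, dbfn=":memory:", from_string=True, force=True,
        keep_order=True, merge_strategy="create_unique",
    )
    sequence = None
    seq_id = None
    if fasta_text:
        from io import StringIO

        fasta_record = next(SeqIO.parse(StringIO(fasta_text.lstrip("\n")), "fasta"))
        sequence = str(fasta_record.seq)
        seq_id = fasta_record.id

    features = []
    skipped = 0
    accession = None
    length = None
    topology = "linear"
    for directive in db.directives:
        m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", directive)
        if m:
            accession = m.group(1)
            length = int(m.group(3))
    for f in db.all_features(order_by=("start", "end")):
        if f.featuretype == "region":
            topology = "circular" if "Is_circular=true" in str(f) else topology
            continue
        if f.featuretype not in RETAINED_KINDS:
            continue
        attrs = {k: [_gff_unescape(v) for v in vals] for k, vals in f.attributes.items()}
        primary = (attrs.get("locus_tag") or attrs.get("ID") or [None])[0]
        if primary is None:
            skipped += 1
            log.warning("GFF3 %s: %s feature at %d..%d lacks ID/locus_tag; skipped",
                        gff_path, f.featuretype, f.start, f.end)
            continue
        if accession is None:
            accession = f.seqid
        alt = list(attrs.get("protein_id", []))
        for xref in attrs.get("Dbxref", []):
            alt.append(xref.split(":", 1)[-1])
        features.append(GeneFeature(
            primary_id=primary,
            start=f.start - 1,          # GFF3 1-based inclusive -> half-open
            end=f.end,
            strand="-" if f.strand == "-" else "+",
            kind=f.featuretype,
            alt_ids=tuple(alt),
            trivial_name=(attrs.get("Name") or [None])[0],
            product=(attrs.get("product") or [None])[0],
            cog_category=(attrs.get("cog_category") or [None])[0],
            pfam_domains=_parse_pfam_field((attrs.get("pfam_domains") or [None])[0]),
            location_prediction=(attrs.get("sub_location") or [None])[0],
            translation=(attrs.get("translation") or [None])[0],
        ))
    if accession is None:
        raise ParseError(f"GFF3 {gff_path} contains no usable features")
    if seq_id is not None and seq_id != accession:
        raise ContextmapError(
            f"seqid mismatch: GFF3 declares '{accession}' but FASTA record is '{seq_id}'"
        )
    if sequence is not None:
        length = len(sequence)
    if length is None:
        length = max(f.end for f in features)
    log.info("read_gff3 %s: %d features, %d skipped", gff_path, len(features), skipped)
    return GenomeRecord(
        accession=accession, length=length, features=features,
        sequence=sequence, topology=topology,
    ), skipped


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_KINDS = ("cog", "pfam", "location", "idmap")


def read_annotation_table(path, kind):
    """Read a two-column TSV (identifier, value) into a mapping.

    ``kind`` selects the target attribute: ``cog`` (single letter),
    ``pfam`` (``ACC:start-end;...`` strings), ``location`` (category), or
    ``idmap`` (extra alternate identifier, e.g. a Uniprot accession).
    A duplicated identifier with conflicting values is an error.
    """
    if kind not in ANNOTATION_KINDS:
        raise ContextmapError(
            f"unknown annotation kind '{kind}'; expected one of {ANNOTATION_KINDS}"
        )
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ParseError(f"annotation table {path} needs an id column and a value column")
    mapping = {}
    for row in frame.itertuples(index=False):
        key, value = row[0], row[1]
        if key in mapping and mapping[key] != value:
            raise ContextmapError(
                f"annotation table {path}: identifier '{key}' maps to both "
                f"'{mapping[key]}' and '{value}'"
            )
        mapping[key] = value
    return mapping


def apply_annotation(genomes, mapping, kind) -> ResolutionReport:
    """Merge an annotation mapping into matching features, in place.

    Unmatched identifiers are reported, never raised.
    """
    if kind not in ANNOTATION_KINDS:
        raise ContextmapError(f"unknown annotation kind '{kind}'")
    index = build_index(genomes)
    report = ResolutionReport()
    for key, value in mapping.items():
        hits = index.lookup(key)
        if not hits:
            report.unresolved.append(key)
            continue
        for _, feature in hits:
            if kind == "cog":
                feature.cog_category = value
            elif kind == "pfam":
                feature.pfam_domains = _parse_pfam_field(value)
            elif kind == "location":
                feature.location_prediction = value
            elif kind == "idmap":
                if value not in feature.alt_ids:
                    feature.alt_ids = feature.alt_ids + (value,)
    return report


# ---------------------------------------------------------------------------
# Identifier index and query resolution
# ---------------------------------------------------------------------------


class IdentifierIndex:
    """Case-insensitive identifier -> (accession, feature) lookup.

    Collisions across genomes are retained as multi-hits and surface at
    lookup time; they are never silently resolved.
    """

    def __init__(self):
        self._ids = {}
        self._all = []  # (accession, feature) in load order

    def add_genome(self, genome: GenomeRecord):
        for feature in genome.features:
            self._all.append((genome.accession, feature))
            for token in feature.all_ids():
                self._ids.setdefault(token.lower(), []).append(
                    (genome.accession, feature)
                )

    def lookup(self, token: str) -> list:
        return list(self._ids.get(token.strip().lower(), []))

    def known(self, token: str) -> bool:
        return token.strip().lower() in self._ids

    def all_features(self):
        return list(self._all)

    def __len__(self):
        return len(self._ids)


def build_index(genomes) -> IdentifierIndex:
    """Index every primary and alternate identifier of a genome collection."""
    genomes = list(genomes)
    if not genomes:
        raise ContextmapError("build_index requires at least one genome")
    seen = set()
    for g in genomes:
        if g.accession in seen:
            raise ContextmapError(f"duplicate genome accession '{g.accession}'")
        seen.add(g.accession)
    index = IdentifierIndex()
    for genome in genomes:
        index.add_genome(genome)
    return index


def resolve_identifiers(index: IdentifierIndex, raw: str):
    """Resolve whitespace/newline-separated identifier tokens.

    Returns ``(hits, report)`` where ``hits`` is an ordered list of
    ``(accession, feature)`` preserving input order and duplicates, and the
    report lists unresolved tokens verbatim and ambiguous multi-hits.
    """
    hits = []
    report = ResolutionReport()
    for token in raw.split():
        found = index.lookup(token)
        if not found:
            report.unresolved.append(token)
        elif len(found) > 1:
            report.ambiguous[token] = found
        else:
            hits.append(found[0])
    return hits, report


def parse_region_queries(raw: str, strict_tabs: bool = False):
    """Parse region triples ``accession<TAB>start<TAB>stop`` (1-based inclusive).

    Returns ``(regions, report)``; swapped start/stop is tolerated with a
    note, non-integer coordinates are reported per line with line numbers.
    """
    regions = []
    report = ResolutionReport()
    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t") if strict_tabs else line.split()
        parts = [p for p in parts if p != ""]
        if len(parts) < 3:
            report.unresolved.append(
                f"line {lineno}: expected 'accession start stop', got {line!r}"
            )
            continue
        acc, s_txt, e_txt = parts[0], parts[1], parts[2]
        try:
            s, e = int(s_txt), int(e_txt)
        except ValueError:
            report.unresolved.append(
                f"line {lineno}: non-integer coordinates in {line!r}"
            )
            continue
        if s > e:
            s, e = e, s
            report.notes.append(f"line {lineno}: start > stop, swapped")
        regions.append(RegionQuery(accession=acc, start=s - 1, end=e))
    return regions, report


def search_products(index: IdentifierIndex, query: str):
    """Case-insensitive substring search over products and trivial names.

    Results are sorted by (genome accession, start).
    """
    if not query:
        raise ContextmapError("search_products requires a non-empty query")
    needle = query.lower()
    out = []
    for accession, feature in index.all_features():
        hay = " ".join(t for t in (feature.product, feature.trivial_name) if t)
        if needle in hay.lower():
            out.append((accession, feature))
    out.sort(key=lambda pair: (pair[0], pair[1].start))
    return out
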