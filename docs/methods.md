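# Methods

This note documents the models, conventions and design choices behind
`contextmap`, the way they are implemented, and what the test suite does
and does not demonstrate.

## Coordinates and genome model

All internal coordinates are 0-based half-open on the forward strand;
every user-facing surface (GenBank, GFF3, region triples, exported tables,
FASTA headers) is 1-based inclusive, converted exactly once at the I/O
boundary. This removes off-by-one risk from window arithmetic while
matching what the source formats and their users expect.

A genome is an accession, a length, an optional sequence, and a
start-sorted list of gene features. Features carry a primary identifier
(locus tag), any number of alternate identifiers (protein IDs, GI-like
numeric codes, Uniprot accessions merged in from identifier-mapping
tables), and optional annotation (product, trivial name, COG class, Pfam
domains, sub-cellular location, stored translation). Compound
`join(...)` locations are collapsed to their outer envelope and flagged;
bacterial genes essentially never splice, and a context map needs one
glyph per gene. Non-CDS features (tRNA/rRNA/ncRNA) are retained with
their kind and drawn in a neutral style. A record loaded without sequence
stays usable for mapping; sequence-dependent operations (GC, upstream,
on-the-fly translation) raise a capability error naming the genome.

GenBank parsing is delegated to Biopython, GFF3 to gffutils (in-memory
database), FASTA to Biopython; annotation tables go through pandas. The
GFF3 *writer* in the fixture generator is plain line emission with
RFC-style percent-escaping of `; = % & ,` so that products containing
commas survive the attribute round-trip.

## Context windows and orientation

The context of an anchor is the interval
`[anchor.start − range, anchor.end + range)` clamped to the genome; a gene
is a member when it overlaps the window by ≥ 1 nt (glyphs are clipped at
the window edge at render time). The range is measured from the anchor's
endpoints, not its midpoint, so the anchor gene is always fully inside its
own window. Region queries become windows directly; their anchor is the
member whose midpoint is nearest the region midpoint (ties to the
leftmost), and a region covering no genes stays a valid, empty row.

Enforcing identical anchor orientation never touches genomic coordinates.
A row whose anchor lies on the minus strand is marked `flipped`, and all
display positions go through the reflection `x ↦ (window_start +
window_end) − x` with drawn strands inverted. The operation is the
identity for plus-strand anchors and idempotent for minus-strand ones;
overlay elements pass through the same transform, which is what makes
"element placement commutes with row flipping" a testable invariant.

## Sequence operations

GC% is `100·(G+C)/(A+C+G+T)` over the gene's forward-strand slice with
IUPAC ambiguity codes excluded from numerator and denominator; an
all-ambiguous slice has undefined GC and renders neutral.

Upstream regions read 5′→3′ toward the start codon: `[start−L, start)`
for plus-strand genes, `[end, end+L)` reverse-complemented for
minus-strand genes. Truncation at the nearest intruding neighbor (any
strand, any kind — a conservative promoter-region definition) is optional
and on by default, because motif discovery on upstream sets should not
swallow coding sequence; the untruncated mode exists because real
regulatory sites do occur inside the 5′ ends of coding regions. Circular
genomes wrap across the origin (the wrapped copy of any feature,
including the gene itself, still truncates); linear genomes clamp at
their ends and report the end as the truncation cause.

Translation uses the bacterial genetic code (NCBI table 11) with
alternative start codons (GTG/TTG) read as methionine in first position.
An internal stop during on-the-fly translation is an error naming the
gene — it signals a pseudo-gene or a coordinate fault, and silently
emitting `*` would poison downstream FASTA consumers.

## Trees

Newick handling is delegated to dendropy with underscores preserved.
Leaf labels bind to genes by exact whole-label match first, then by
delimited tokens — split on `|` and whitespace first (so locus tags that
themselves contain underscores stay intact), then additionally on `_`.
A leaf matching zero or several distinct genes is reported, never
guessed, and keeps a placeholder row so the drawn tree can never
disagree with the row stack. Trees are kept exactly as uploaded: no
re-rooting, no ladderizing. Pruning suppresses single-child internal
nodes, summing branch lengths, and preserves the relative order of kept
leaves. Layout gives leaves y = 0,1,2,… in depth-first order, internal
nodes the mean of their children's y, and x either node depth
(cladogram) or cumulative branch length with missing lengths defaulting
to 1 (phylogram).

## Overlays, gradients, ranking, colors

Element tracks come from 1-based inclusive TSV
(`accession start stop strand score [label]`) or standard 0-based BED
(name column 4, score column 5); both normalize to the same internal
elements. Elements on genomes that are not loaded are kept — a track may
legitimately span more genomes than the current view. Quantitative
tables are strict: duplicate gene IDs and non-numeric values are errors
with line numbers, because silently averaging expression ratios would be
worse than failing.

The gradient is piecewise-linear through three colors, red (255,0,0) →
yellow (255,255,0) → green (0,200,0), clamped at the domain endpoints.
For the default symmetric-about-zero transform the midpoint color sits at
value 0 (the natural neutral point of log-ratios); the linear transform
puts it at the domain midpoint. A degenerate domain maps everything to
the midpoint color.

Ranking is a stable sort: the key is the row's maximum element score
(best-site ranking) or the anchor gene's quantitative value; rows without
a key sink to the bottom in their original relative order, and the output
is always a permutation of the input. Max was chosen as the element
aggregate because a single strong site is what makes a row interesting;
per-row sums would reward windows that merely contain many weak matches.

Category colors (Pfam, location) are a pure function of the identifier
string: slot = CRC32(id) mod palette size over a 32-color qualitative
palette, with deterministic forward-probing (applied in sorted order, so
the result is independent of input order) when two identifiers in one
figure collide; overflow repeats colors and flags the legend. COG classes
use a fixed 26-letter palette. Every figure gets a `identifier → hex`
legend TSV written next to it.

## Rendering

`build_scene` converts rows (+ optional tree layout) into a
resolution-independent scene — glyph coordinates in px, fills resolved,
labels truncated with a middle ellipsis when they outgrow their glyph
(full text stays in the tooltip) — and `render_linear_svg` serializes it.
Determinism is a contract: floats are printed with fixed two-decimal
precision, a single generic sans-serif family is embedded, and identical
scenes yield byte-identical SVG. Gene glyphs are strand-directed pentagon
arrows with class `gene` and a `data-identifier` attribute; tooltips
(SVG `<title>`) carry identifier, alternate IDs, product and COG. Rows
are 64 px bands: element lane above, gene lane in the middle, the
quantitative bar below the genes.

Circular maps put position 0 at 12 o'clock with angles increasing
clockwise, `angle(p) = 360°·p/L`. Plus-strand ORFs draw in an outer blue
ring, minus-strand in grey below it, highlighted genes as green marks
outside, the windowed GC% profile (default 2 kb window, 1 kb step,
auto-scaled to its own min–max) as a red radial polyline, and element
midpoints as green dots.

PNG/PDF conversion is delegated to the optional `cairosvg` backend; when
it is absent the operation fails with a clear SVG-only capability message
and the CLI treats that as a warning, not an error.

## Synthetic fixtures

The generators are pure functions of their seed. A synthetic genome packs
non-overlapping genes of 300–2400 nt (multiples of 3, random strands,
gaps ≥ 1 nt, ~40% of slack distributed randomly); coding strands start
with ATG, end with a stop, and contain no internal stop, so translations
are exact oracles. Genome GC is steered to the target by flipping
intergenic bases after assembly and lands within ±3 percentage points
whenever the intergenic fraction allows. Products draw from a fixed
vocabulary that includes case-study-like strings ("beta-galactosidase",
"transcriptional regulator") so demo figures read naturally.

The conserved-context generator embeds an operon-like block of named
roles (default regulator–transporter–hydrolase–kinase, anchor = the
regulator) into each of n genomes between random background genes, with
at most one perturbation per genome at the divergence rate: loss of a
non-anchor role, insertion of a background gene into the block, or a
whole-block inversion. A random binary tree over the genomes is emitted
whose leaf labels embed the anchor locus tags behind `|`.

The overlay generator plants one scored site 40–70 nt upstream of a
random site-fraction subset of anchors (14–22 nt long, on the anchor's
strand, score uniform in the configured range), then assigns expression
ratios: site-bearing anchors uniform in −3.0…−1.5, all others in
−0.3…0.3, and one siteless decoy in −4.0…−3.5 — the strongest responder
with no site, emulating an indirectly regulated operon. Ranking
ascending therefore must put the decoy first and the site-bearing genes
directly after it, which is the end-to-end check the acceptance suite
runs.

What the fixtures do **not** emulate: realistic codon usage or GC skew,
operon transcription structure, motif statistics, overlapping genes,
pseudo-genes, assembly gaps, or multi-replicon genomes. Passing tests
demonstrate the correctness of the coordinate arithmetic, transforms and
renderers on clean input, not robustness to every pathology of real
annotation files.

## Problem sizes and numerical choices

The validation suite uses 10–100 genomes of 16–30 kb with 10–15 genes
each, 500-case upstream sweeps, 1000-slice GC sweeps, trees up to 64
leaves and 50-run tree-map sweeps; the acceptance script repeats the
same measurements from a single seed. Circular angles are exact closed
forms and are checked to 1e-9 degrees; gradient channels are checked
against the closed-form interpolation at integer precision; SVG
determinism is checked as byte equality. Ties are broken consistently
everywhere: leftmost member for region anchors, input order for equal
ranking keys, sorted identifier order for color probing.

## Known limitations

- GFF3 input assumes one sequence region per file (single-replicon
  bacterial chromosomes/plasmids, one file each).
- Features wrapping the origin of a circular genome are flagged but
  rendered by their envelope; windows never wrap the origin.
- Leaf binding requires identifiers to appear as whole delimited tokens;
  arbitrary substrings do not bind (by design, to avoid false matches).
- No BLAST, motif discovery, operon prediction or ortholog detection:
  identifier lists, trees and scored sites are consumed as given,
  produced by whatever external tool the analysis uses.
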