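# contextmap

Comparative genomic-context maps for bacteria, as an offline library and CLI.

Conserved gene context — which genes flank a gene of interest, and whether
that neighborhood is preserved across species — is one of the most
informative signals in microbial genome analysis. It guides function
annotation, the discovery of transcription-factor binding sites, and the
sequence-based reconstruction of regulons. `contextmap` builds the figures
and data exports that this kind of manual analysis runs on:

- **Linear comparative context maps.** For a set of anchor genes (given as
  identifier lists, region triples `accession<TAB>start<TAB>stop`, product
  searches, or the leaves of a Newick gene tree), each row shows the genes
  overlapping a symmetric window of ±`range` nucleotides around one anchor,
  drawn as strand-directed arrows. Rows can be mirrored so every anchor
  reads left-to-right; genes can be labelled by locus tag, trivial name or
  alternate identifier and colored by COG class, Pfam domain, sub-cellular
  location prediction, or GC%.
- **Tree-aligned rows.** An uploaded Newick tree is drawn beside the rows,
  with one context row per leaf in exact leaf order, so clades and
  neighborhood conservation can be read together.
- **Overlay tracks and ranked maps.** Positioned, scored elements (e.g.
  predicted binding sites) appear as purple strand-arrows above the genes;
  gene-keyed quantitative data (e.g. microarray log-ratios) fill a
  red→yellow→green gradient bar beneath them (red = down-regulated, the
  midpoint anchored at 0 for ratio-like data). Rows can be ranked by best
  element score or by the anchor's expression value, so predictions and
  measurements can be interpreted in light of each other.
- **Circular genome maps**: plus-strand ORFs (blue), minus-strand ORFs
  (grey), highlighted genes (green), a windowed GC% profile (red) and
  element dots, with position 0 at 12 o'clock and angle = 360°·p/L.
- **Data export**: upstream regions (optionally truncated at the nearest
  neighboring gene, so promoter searches do not swallow coding sequence),
  protein sequences, and annotation tables, for any selected gene set —
  no map required.

Everything reads local files: GenBank flat files or GFF3(+FASTA) for
genomes, TSV/BED for overlay tracks, TSV for annotation (COG, Pfam,
location, identifier mappings). All SVG output is deterministic —
identical inputs give byte-identical documents — and carries
machine-readable `data-identifier` attributes plus embedded tooltips.

A synthetic-fixture generator (`contextmap fixtures …`) produces genomes,
conserved-context genome sets with matching trees, and planted
binding-site/expression overlays with full ground-truth manifests, so
every part of the pipeline can be exercised and validated without any
downloads.

## Worked example

Generate a five-genome conserved-context fixture set with planted overlay
data, then draw a tree-aligned map and a ranked map:

```bash
contextmap fixtures contexts --seed 11 --n-genomes 5 --out-dir demo
contextmap fixtures overlays --seed 12 --contexts-dir demo
contextmap map --genomes demo/SYNC011G00.gbff --genomes demo/SYNC011G01.gbff \
    --genomes demo/SYNC011G02.gbff --genomes demo/SYNC011G03.gbff \
    --genomes demo/SYNC011G04.gbff \
    --tree demo/tree.nwk --orient --range 8000 --color-by cog --out demo/map.svg
```

which prints

```
wrote 5 genomes + tree to demo
wrote elements.tsv, quant.tsv, truth.json to demo
wrote demo/map.svg (5 rows)
```

`demo/map.svg` holds five context rows, one per tree leaf in leaf order,
every anchor pointing right; `demo/map.svg.legend.tsv` lists the COG color
scheme used (`identifier<TAB>color`, e.g. `K  #fadcfc`). Ranking the same
anchors by expression ratio with binding-site arrows overlaid:

```bash
contextmap map --genomes demo/SYNC011G00.gbff ... \
    --ids "SYNC011G00_0005 SYNC011G01_0009 ..." \
    --quant demo/quant.tsv --elements demo/elements.tsv \
    --rank-by quant_value --out demo/ranked.svg
# -> wrote demo/ranked.svg (5 rows)
```

puts the most strongly down-regulated anchors at the top; the planted
fixture guarantees that site-bearing genes and one siteless decoy occupy
that top band. Exporting an upstream region for motif discovery:

```bash
contextmap export --genomes demo/SYNC011G00.gbff \
    --ids SYNC011G00_0005 --what upstream --length 200 --out demo/up.fa
```

```
>SYNC011G00_0005|genome=SYNC011G00|region=4317..4516|strand=+|truncated=false
CTGACGGTAAGCATGGTGTATCATTTTAAGAGCGACTTCATGGTTTCTTCGAATTTCAGT...
```

The header gives the genome, the 1-based inclusive interval, the strand and
whether a neighboring gene truncated the region. The same operations are
available as library functions (`contextmap.extract_context`,
`attach_overlays`, `rank_rows`, `render_linear_svg`, …); CLI output is
byte-identical to the corresponding API calls.

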