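"""Context windows, orientation, GC%, upstream regions, translation."""

import random

import pytest

from contextmap import (
    ContextmapError,
    RegionQuery,
    TranslationError,
    compute_gene_gc,
    extract_context,
    extract_context_for_region,
    extract_upstream,
    get_protein_sequence,
    normalize_orientation,
    revcomp,
)
from contextmap import fixtures as fx
from contextmap.genome_io import GeneFeature, GenomeRecord


def brute_force_members(genome, ws, we):
    return [f for f in genome.features if f.start < we and f.end > ws]


def test_zero_range_window_equals_anchor_interval(small_genome):
    genome, _ = small_genome
    anchor = genome.features[3]
    w = extract_context(genome, anchor, 0)
    assert (w.window_start, w.window_end) == (anchor.start, anchor.end)
    assert anchor in w.members
    assert not w.flipped


def test_window_membership_matches_brute_force_scan():
    rng = random.Random(99)
    for seed in range(10):
        genome, _ = fx.synth_genome(seed=1000 + seed, n_genes=15, length=25000)
        for _ in range(10):
            anchor = rng.choice(genome.features)
            range_nt = rng.choice([0, 500, 2500, 10000])
            w = extract_context(genome, anchor, range_nt)
            assert w.members == brute_force_members(genome, w.window_start, w.window_end)
            assert w.window_start == max(0, anchor.start - range_nt)
            assert w.window_end == min(genome.length, anchor.end + range_nt)


def test_window_clamps_at_genome_boundaries(small_genome):
    genome, _ = small_genome
    first = genome.features[0]
    w = extract_context(genome, first, 10_000_000)
    assert w.window_start == 0
    assert w.window_end == genome.length


def test_foreign_anchor_is_rejected(small_genome, genome_set):
    genome, _ = small_genome
    other = genome_set[0][0]
    with pytest.raises(ContextmapError, match=other.features[0].primary_id):
        extract_context(genome, other.features[0], 100)


def test_region_window_picks_midpoint_nearest_anchor(small_genome):
    genome, _ = small_genome
    gene = genome.features[5]
    region = RegionQuery(accession=genome.accession, start=gene.start, end=gene.end)
    w = extract_context_for_region(genome, region)
    assert w.anchor is gene
    # a region in a gene-free gap yields an anchorless but renderable row
    gaps = [(a.end, b.start) for a, b in zip(genome.features, genome.features[1:])
            if b.start - a.end > 10]
    ge, gs = gaps[0]
    empty = extract_context_for_region(
        genome, RegionQuery(accession=genome.accession, start=ge + 1, end=gs - 1))
    assert empty.anchor is None and empty.members == []


def test_region_members_match_brute_force(small_genome, rng):
    genome, _ = small_genome
    for _ in range(25):
        a = rng.randint(0, genome.length - 2)
        b = rng.randint(a + 1, genome.length)
        w = extract_context_for_region(
            genome, RegionQuery(accession=genome.accession, start=a, end=b))
        assert w.members == brute_force_members(genome, a, b)


class TestOrientation:
    def _window_with_strand(self, small_genome, strand):
        genome, _ = small_genome
        anchor = next(f for f in genome.features if f.strand == strand)
        return extract_context(genome, anchor, 5000)

    def test_plus_strand_anchor_is_identity(self, small_genome):
        w = self._window_with_strand(small_genome, "+")
        assert normalize_orientation(w) is w

    def test_minus_strand_flip_is_idempotent(self, small_genome):
        w = self._window_with_strand(small_genome, "-")
        once = normalize_orientation(w)
        assert once.flipped
        assert normalize_orientation(once) is once
        # member multiset and anchor are preserved; only the transform toggles
        assert once.members == w.members
        assert once.anchor is w.anchor

    def test_flip_reflects_positions_about_window_midline(self, small_genome):
        w = self._window_with_strand(small_genome, "-")
        flipped = normalize_orientation(w)
        total = w.window_start + w.window_end
        for m in w.members:
            d1, d2 = flipped.display_interval(m.start, m.end)
            assert (d1, d2) == (total - m.end, total - m.start)
        first = min(w.members, key=lambda f: f.start)
        display_starts = [flipped.display_interval(m.start, m.end)[0]
                          for m in flipped.sorted_members()]
        assert flipped.sorted_members()[-1] is first
        assert display_starts == sorted(display_starts)


class TestGC:
    def _one_gene_genome(self, seq):
        gene = GeneFeature(primary_id="g1", start=0, end=len(seq), strand="+")
        return GenomeRecord(accession="GCT", length=len(seq), features=[gene],
                            sequence=seq), gene

    def test_all_gc_slice_is_100(self):
        genome, gene = self._one_gene_genome("GGCC")
        assert compute_gene_gc(genome, gene) == 100.0

    def test_all_at_slice_is_0(self):
        genome, gene = self._one_gene_genome("ATAT")
        assert compute_gene_gc(genome, gene) == 0.0

    def test_ambiguity_codes_are_excluded(self):
        genome, gene = self._one_gene_genome("GCNNAT")
        assert compute_gene_gc(genome, gene) == 50.0
        genome2, gene2 = self._one_gene_genome("NNNN")
        assert compute_gene_gc(genome2, gene2) is None

    def test_matches_counting_oracle_and_complements_at(self, small_genome, rng):
        genome, _ = small_genome
        for _ in range(100):
            gene = rng.choice(genome.features)
            got = compute_gene_gc(genome, gene)
            piece = genome.sequence[gene.start:gene.end].upper()
            gc = sum(piece.count(c) for c in "GC")
            at = sum(piece.count(c) for c in "AT")
            assert got == 100.0 * gc / (gc + at)
            assert gene.gc_percent == got
            at_pct = 100.0 * at / (gc + at)
            assert got + at_pct == pytest.approx(100.0)


class TestUpstream:
    def test_plus_strand_direct_slice(self, small_genome):
        genome, _ = small_genome
        gene = next(f for f in genome.features[3:] if f.strand == "+")
        up = extract_upstream(genome, gene, 50, truncate_at_neighbor=False)
        assert up.genomic_interval == (gene.start - 50, gene.start)
        assert up.sequence == genome.sequence[gene.start - 50:gene.start]
        assert not up.truncated

    def test_minus_strand_is_reverse_complement(self, small_genome):
        genome, _ = small_genome
        gene = next(f for f in genome.features[3:] if f.strand == "-")
        up = extract_upstream(genome, gene, 50, truncate_at_neighbor=False)
        fwd = genome.sequence[gene.end:gene.end + 50]
        assert up.sequence == revcomp(fwd)
        assert revcomp(up.sequence) == fwd

    def test_neighbor_truncation_length_and_cause(self):
        seq = "A" * 2000
        left = GeneFeature(primary_id="nL", start=700, end=950, strand="+")
        gene = GeneFeature(primary_id="g", start=1000, end=1300, strand="+")
        genome = GenomeRecord(accession="UT", length=2000,
                              features=[left, gene], sequence=seq)
        up = extract_upstream(genome, gene, 200, truncate_at_neighbor=True)
        assert len(up.sequence) == 50
        assert up.truncated and up.truncation_cause == "nL"
        free = extract_upstream(genome, gene, 200, truncate_at_neighbor=False)
        assert len(free.sequence) == 200 and not free.truncated

    def test_matches_slicing_oracle_on_random_triples(self, small_genome, rng):
        genome, _ = small_genome
        for _ in range(200):
            gene = rng.choice(genome.features)
            L = rng.choice([0, 30, 100, 300, 1000])
            truncate = rng.random() < 0.5
            up = extract_upstream(genome, gene, L, truncate)
            a, b = up.genomic_interval
            expected = genome.sequence[a:b]
            if gene.strand == "-":
                expected = revcomp(expected)
            assert up.sequence == expected
            assert len(up.sequence) <= L
            # never overlaps the gene's own interval
            assert b <= gene.start or a >= gene.end
            if truncate:
                for f in genome.features:
                    if f is not gene:
                        assert f.end <= a or f.start >= b

    def test_circular_genome_wraps_across_origin(self):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        gene = GeneFeature(primary_id="g", start=30, end=330, strand="+")
        genome = GenomeRecord(accession="CIRC", length=500, features=[gene],
                              sequence=seq, topology="circular")
        up = extract_upstream(genome, gene, 100, truncate_at_neighbor=False)
        assert up.genomic_interval == (-70, 30)
        assert up.sequence == seq[430:] + seq[:30]


class TestProtein:
    def test_stored_translation_passthrough(self):
        gene = GeneFeature(primary_id="p", start=0, end=9, strand="+",
                           translation="MKV")
        assert get_protein_sequence(gene) == "MKV"

    def test_on_the_fly_translation_with_stop_trim(self):
        seq = "ATGAAAGTGTAA"
        gene = GeneFeature(primary_id="p", start=0, end=12, strand="+")
        genome = GenomeRecord(accession="TR", length=12, features=[gene],
                              sequence=seq)
        assert get_protein_sequence(gene, genome) == "MKV"
        minus = GeneFeature(primary_id="m", start=0, end=12, strand="-")
        genome2 = GenomeRecord(accession="TR2", length=12, features=[minus],
                               sequence=revcomp(seq))
        assert get_protein_sequence(minus, genome2) == "MKV"

    def test_internal_stop_raises_naming_gene(self):
        seq = "ATGTAAGTGTAA"
        gene = GeneFeature(primary_id="pseudo", start=0, end=12, strand="+")
        genome = GenomeRecord(accession="TR3", length=12, features=[gene],
                              sequence=seq)
        with pytest.raises(TranslationError, match="pseudo"):
            get_protein_sequence(gene, genome)

    def test_fixture_proteins_match_generator_manifest(self, small_genome):
        genome, manifest = small_genome
        for feature, mf in zip(genome.features, manifest["features"]):
            stored = feature.translation
            feature.translation = None      # force on-the-fly translation
            try:
                assert get_protein_sequence(feature, genome) == mf["translation"]
            finally:
                feature.translation = stored
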