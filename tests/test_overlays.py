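"""Overlay tracks: reading dialects, gradients, attachment, ranking, colors."""

import random

import pytest

from contextmap import (
    ColorGradient,
    ContextmapError,
    ParseError,
    QuantTrack,
    assign_category_colors,
    attach_overlays,
    build_index,
    extract_context,
    gradient_for_track,
    normalize_orientation,
    rank_rows,
    read_element_track,
    read_quant_table,
    value_to_color,
)
from contextmap import fixtures as fx
from contextmap.overlays import GREEN, RED, YELLOW, legend_tsv, row_rank_key


class TestElementTrack:
    def test_tsv_one_based_conversion(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("NC_X\t11\t20\t+\t7.5\tsiteA\n")
        track = read_element_track(p, "tsv")
        e = track.elements[0]
        assert (e.start, e.end, e.strand, e.score, e.label) == (10, 20, "+", 7.5, "siteA")

    def test_bed_dialect_is_equivalent(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("NC_X\t10\t20\tsiteA\t7.5\t+\n")
        e = read_element_track(p, "bed").elements[0]
        assert (e.start, e.end, e.strand, e.score, e.label) == (10, 20, "+", 7.5, "siteA")

    def test_cross_dialect_round_trip(self, tmp_path, rng):
        rows_tsv, rows_bed = [], []
        for i in range(200):
            acc = f"NC_{rng.randint(1, 5)}"
            start = rng.randint(0, 90000)
            end = start + rng.randint(5, 40)
            strand = rng.choice(["+", "-"])
            score = round(rng.uniform(0, 100), 3)
            rows_tsv.append(f"{acc}\t{start + 1}\t{end}\t{strand}\t{score}\ts{i}")
            rows_bed.append(f"{acc}\t{start}\t{end}\ts{i}\t{score}\t{strand}")
        t = tmp_path / "x.tsv"
        b = tmp_path / "x.bed"
        t.write_text("\n".join(rows_tsv) + "\n")
        b.write_text("\n".join(rows_bed) + "\n")
        assert read_element_track(t, "tsv") == read_element_track(b, "bed")

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("NC_X\t1\t10\t+\t5.0\nNC_X\tone\tten\t+\t5.0\n")
        with pytest.raises(ParseError, match="line 2"):
            read_element_track(p, "tsv")


class TestQuantTrack:
    def test_domain_is_min_max(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("gA\t-2.0\ngB\t0.0\ngC\t2.0\n")
        track = read_quant_table(p)
        assert track.value_domain == (-2.0, 2.0)

    def test_degenerate_single_entry_domain(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("gA\t5\n")
        track = read_quant_table(p)
        assert track.value_domain == (5.0, 5.0)
        grad = gradient_for_track(track)
        assert value_to_color(grad, 5.0) == grad.mid_color

    def test_duplicate_id_and_bad_value_errors(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("gA\t1\ngA\t2\n")
        with pytest.raises(ContextmapError, match="gA"):
            read_quant_table(dup)
        bad = tmp_path / "bad.tsv"
        bad.write_text("gA\t1\ngB\tnotanumber\n")
        with pytest.raises(ParseError, match="line 2"):
            read_quant_table(bad)

    def test_random_values_domain_oracle(self, tmp_path, rng):
        vals = {f"g{i}": round(rng.uniform(-50, 50), 4) for i in range(500)}
        p = tmp_path / "big.tsv"
        p.write_text("\n".join(f"{k}\t{v}" for k, v in vals.items()) + "\n")
        track = read_quant_table(p)
        assert track.value_domain == (min(vals.values()), max(vals.values()))


class TestGradient:
    GRAD = ColorGradient(domain=(-2.0, 0.0, 2.0))

    def test_endpoints_are_exact(self):
        assert value_to_color(self.GRAD, -2.0) == RED
        assert value_to_color(self.GRAD, -99.0) == RED       # clamp
        assert value_to_color(self.GRAD, 2.0) == GREEN
        assert value_to_color(self.GRAD, 99.0) == GREEN
        assert value_to_color(self.GRAD, 0.0) == YELLOW

    def test_interior_matches_closed_form_interpolation(self):
        rng = random.Random(8)
        for _ in range(200):
            v = rng.uniform(-2.0, 2.0)
            got = value_to_color(self.GRAD, v)
            if v < 0:
                t = (v + 2.0) / 2.0
                expected = tuple(int(round(RED[i] + (YELLOW[i] - RED[i]) * t))
                                 for i in range(3))
            elif v == 0:
                expected = YELLOW
            else:
                t = v / 2.0
                expected = tuple(int(round(YELLOW[i] + (GREEN[i] - YELLOW[i]) * t))
                                 for i in range(3))
            assert got == expected

    def test_monotone_per_channel_on_each_half(self):
        lo_half = [value_to_color(self.GRAD, v / 100.0) for v in range(-200, 1)]
        for ch in range(3):
            channel = [c[ch] for c in lo_half]
            assert channel == sorted(channel) or channel == sorted(channel, reverse=True)

    def test_symmetric_transform_anchors_mid_at_zero(self):
        track = QuantTrack(values={"a": -3.0, "b": 1.0})
        grad = gradient_for_track(track)
        assert grad.domain == (-3.0, 0.0, 1.0)
        assert value_to_color(grad, 0.0) == YELLOW


class TestAttach:
    def _rows_with_track(self, conserved_set, tmp_path, orient=False):
        genomes, manifest, _ = conserved_set
        el, quant, truth = fx.synth_overlays(seed=9, genomes=genomes,
                                             context_manifest=manifest)
        (tmp_path / "e.tsv").write_text(el)
        (tmp_path / "q.tsv").write_text(quant)
        track = read_element_track(tmp_path / "e.tsv", "tsv")
        qtrack = read_quant_table(tmp_path / "q.tsv")
        by_acc = {g.accession: g for g in genomes}
        rows = []
        for pg in manifest["genomes"]:
            genome = by_acc[pg["accession"]]
            anchor = next(f for f in genome.features
                          if f.primary_id == pg["anchor_id"])
            row = extract_context(genome, anchor, 6000)
            rows.append(normalize_orientation(row) if orient else row)
        attach_overlays(rows, track, qtrack)
        return rows, truth

    def test_planted_sites_recovered_at_exact_positions(self, conserved_set, tmp_path):
        rows, truth = self._rows_with_track(conserved_set, tmp_path)
        for row, entry in zip(rows, truth):
            if entry["has_site"]:
                genomic = [(p.element.start, p.element.end, p.element.score)
                           for p in row.placed_elements]
                assert (entry["site_start"], entry["site_end"], entry["score"]) in genomic
            assert row.member_values[row.anchor.primary_id] == entry["ratio"]

    def test_flipped_rows_mirror_elements_and_reverse_arrows(self, conserved_set, tmp_path):
        rows, truth = self._rows_with_track(conserved_set, tmp_path, orient=True)
        for row in rows:
            total = row.window_start + row.window_end
            for p in row.placed_elements:
                if row.flipped:
                    assert p.display_start == total - p.element.end
                    assert p.display_end == total - p.element.start
                    if p.element.strand in "+-":
                        assert p.display_strand != p.element.strand
                else:
                    assert (p.display_start, p.display_end) == (p.element.start,
                                                                p.element.end)

    def test_elements_outside_all_windows_attach_nowhere(self, conserved_set, tmp_path):
        genomes, manifest, _ = conserved_set
        far = f"{genomes[0].accession}\t{genomes[0].length - 4}\t{genomes[0].length}\t+\t1.0\touter\n"
        (tmp_path / "far.tsv").write_text(far)
        track = read_element_track(tmp_path / "far.tsv", "tsv")
        genome = genomes[0]
        row = extract_context(genome, genome.features[0], 1000)
        attach_overlays([row], track, None)
        assert row.placed_elements == []


class TestRanking:
    def _rows(self, conserved_set, values):
        genomes, manifest, _ = conserved_set
        by_acc = {g.accession: g for g in genomes}
        rows = []
        for pg, v in zip(manifest["genomes"], values):
            genome = by_acc[pg["accession"]]
            anchor = next(f for f in genome.features
                          if f.primary_id == pg["anchor_id"])
            row = extract_context(genome, anchor, 2000)
            if v is not None:
                row.member_values[anchor.primary_id] = v
            rows.append(row)
        return rows

    def test_simple_ascending_order(self, conserved_set):
        rows = self._rows(conserved_set, [3, 1, 2, None, None, None])
        ranked = rank_rows(rows, "quant_value", "ascending")
        assert ranked[:3] == [rows[1], rows[2], rows[0]]
        assert ranked[3:] == rows[3:]        # keyless sink, order preserved

    def test_all_tied_preserves_input_order(self, conserved_set):
        rows = self._rows(conserved_set, [5, 5, 5, 5, 5, 5])
        assert rank_rows(rows, "quant_value") == rows

    def test_matches_stable_sort_oracle(self, conserved_set, rng):
        for _ in range(25):
            values = [rng.choice([None, rng.randint(0, 5)]) for _ in range(6)]
            rows = self._rows(conserved_set, values)
            for direction in ("ascending", "descending"):
                ranked = rank_rows(rows, "quant_value", direction)
                keyed = [(v, i) for i, v in enumerate(values) if v is not None]
                keyed.sort(key=lambda t: t[0], reverse=direction == "descending")
                expected = [rows[i] for _, i in keyed] + [
                    rows[i] for i, v in enumerate(values) if v is None]
                assert ranked == expected
                assert sorted(map(id, ranked)) == sorted(map(id, rows))  # permutation

    def test_element_score_key_uses_row_maximum(self, conserved_set, tmp_path):
        genomes, manifest, _ = conserved_set
        genome = genomes[0]
        row = extract_context(genome, genome.features[1], 4000)
        (tmp_path / "m.tsv").write_text(
            f"{genome.accession}\t{row.window_start + 5}\t{row.window_start + 15}\t+\t3.0\ta\n"
            f"{genome.accession}\t{row.window_start + 30}\t{row.window_start + 40}\t+\t9.0\tb\n")
        attach_overlays([row], read_element_track(tmp_path / "m.tsv", "tsv"), None)
        assert row_rank_key(row, "element_score") == 9.0


class TestCategoryColors:
    def test_same_identifier_same_color_everywhere(self):
        m1, _ = assign_category_colors(["PF00001", "PF00002"], "pfam")
        m2, _ = assign_category_colors(["PF00001", "PF09999"], "pfam")
        assert m1["PF00001"] == m2["PF00001"]

    def test_distinct_identifiers_get_distinct_colors(self):
        ids = [f"PF{i:05d}" for i in range(20)]
        mapping, repeated = assign_category_colors(ids, "pfam")
        assert not repeated
        assert len(set(mapping.values())) == len(ids)

    def test_mapping_is_input_order_invariant(self, rng):
        for _ in range(100):
            ids = [f"CAT{rng.randint(0, 500)}" for _ in range(rng.randint(2, 15))]
            shuffled = ids[:]
            rng.shuffle(shuffled)
            assert assign_category_colors(ids, "pfam") == \
                assign_category_colors(shuffled, "pfam")

    def test_cog_letters_use_fixed_palette(self):
        mapping, _ = assign_category_colors(["K", "E", "K"], "cog")
        from contextmap.overlays import COG_PALETTE
        assert mapping["K"] == COG_PALETTE["K"]
        assert mapping["E"] == COG_PALETTE["E"]

    def test_overflow_flags_repeats(self):
        ids = [f"X{i}" for i in range(40)]   # more ids than palette slots
        mapping, repeated = assign_category_colors(ids, "pfam")
        assert repeated
        assert len(mapping) == 40

    def test_legend_tsv_lists_hex_colors(self):
        mapping, _ = assign_category_colors(["PF00001"], "pfam")
        text = legend_tsv(mapping)
        lines = text.strip().splitlines()
        assert lines[0] == "identifier\tcolor"
        assert lines[1].startswith("PF00001\t#")
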