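"""Synthetic genomes, conserved-context genome sets, trees and overlay data.

Everything here is generated with known ground truth: each generator
returns a *manifest* recording exactly what was planted (identifiers,
intervals, strands, translations, conserved-block composition, site
positions, expression ratios), and the manifests serve as the universal
oracle for the reader, context, export and overlay modules. All output is
a pure function of the seed and parameters.

The conserved-context generator emulates the classic comparative-genomics
situation: an operon-like block of genes (e.g. a sugar-utilization
regulator next to its transporter and hydrolase) conserved across related
species with occasional gene loss, local insertion, or whole-block
inversion. The overlay generator emulates a regulon-reconstruction
experiment: scored binding sites planted upstream of a subset of anchors,
expression ratios down-shifted for site-bearing genes, plus one strongly
responding decoy gene with no site (an indirectly regulated operon).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .context import revcomp
from .errors import ContextmapError
from .genome_io import GeneFeature, GenomeRecord, format_pfam_field

MIN_GENE = 300
MAX_GENE = 2400

PRODUCT_VOCAB = [
    "beta-galactosidase", "transcriptional regulator",
    "PTS system transporter subunit IIA", "ABC transporter permease",
    "galactokinase", "glutamine synthetase", "hypothetical protein",
    "phosphoglycerate kinase", "DNA polymerase III subunit beta",
    "cell division protein", "50S ribosomal protein L1",
    "sugar kinase", "MFS transporter", "two-component response regulator",
    "aminotransferase class I", "acetyltransferase",
]
TRIVIAL_VOCAB = ["galR", "lacR", "rafR", "glnR", "lacZ", "lacA", "lacL",
                 "lacM", "ftsZ", "recA", "gyrA", "dnaA"]
LOCATION_VOCAB = ["cytoplasmic", "membrane", "secreted", "cell wall",
                  "periplasmic"]
COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQRSX"

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass
class GenePlan:
    """Blueprint for one synthetic gene before sequence synthesis."""

    length: int
    strand: str
    kind: str = "CDS"
    product: str = None
    trivial_name: str = None
    cog: str = None
    pfam: tuple = ()
    location: str = None
    role: str = None


def _random_codon(rng, gc_target):
    while True:
        codon = "".join(_pick_base(rng, gc_target) for _ in range(3))
        if codon not in _STOPS:
            return codon


def _pick_base(rng, gc_target):
    if rng.random() < gc_target:
        return rng.choice("GC")
    return rng.choice("AT")


def _coding_sequence(rng, length, gc_target):
    n_codons = length // 3
    body = [_random_codon(rng, gc_target) for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + rng.choice(_STOPS)


def _random_plan(rng, n_genes, length, gc_target):
    budget = length - n_genes - 1   # one guaranteed gap per gene
    consumed = 0
    plans = []
    for i in range(n_genes):
        rest_min = (n_genes - i - 1) * MIN_GENE
        cap = min(MAX_GENE, budget - consumed - rest_min)
        if cap < MIN_GENE:
            raise ContextmapError(
                f"cannot pack {n_genes} genes into {length} nt; "
                "use a larger genome length"
            )
        gene_len = 3 * rng.randint(MIN_GENE // 3, cap // 3)
        consumed += gene_len
        plans.append(GenePlan(
            length=gene_len,
            strand=rng.choice("+-"),
            product=rng.choice(PRODUCT_VOCAB),
            trivial_name=rng.choice(TRIVIAL_VOCAB) if rng.random() < 0.25 else None,
            cog=rng.choice(COG_LETTERS),
            pfam=_random_pfam(rng),
            location=rng.choice(LOCATION_VOCAB),
        ))
    return plans


def _random_pfam(rng):
    n = rng.choice((1, 1, 2))
    out = []
    pos = 1
    for _ in range(n):
        acc = f"PF{rng.randint(1, 2999):05d}"
        lo = pos + rng.randint(0, 20)
        hi = lo + rng.randint(40, 200)
        out.append((acc, lo, hi))
        pos = hi + 5
    return tuple(out)


def _synthesize(rng, accession, plans, length, gc_target, topology,
                id_prefix=None):
    """Lay out gene plans on a genome of a given length and synthesize the
    sequence, returning (GenomeRecord, manifest)."""
    id_prefix = id_prefix or accession
    n = len(plans)
    min_needed = sum(p.length for p in plans) + n + 1
    if min_needed > length:
        raise ContextmapError(
            f"cannot pack {n} genes ({min_needed} nt minimum) into {length} nt; "
            "use a larger genome length"
        )
    # place genes left to right with random gaps, keeping room for the rest
    placements = []
    pos = 0
    for i, plan in enumerate(plans):
        remaining_min = sum(p.length for p in plans[i:]) + (n - i)
        slack = length - pos - remaining_min
        gap = 1 + rng.randint(0, min(max(slack // max(n - i, 1), 0), 400))
        start = pos + gap
        placements.append((start, start + plan.length))
        pos = start + plan.length

    seq = [None] * length
    features = []
    manifest_features = []
    acc_code = hash_seed(accession)            # genome-unique id namespaces
    gi_base = 10_000_000_000 + acc_code * 10_000
    for i, (plan, (start, end)) in enumerate(zip(plans, placements)):
        primary = f"{id_prefix}_{i + 1:04d}"
        if plan.kind == "CDS":
            coding = _coding_sequence(rng, plan.length, gc_target)
            translation = str(Seq(coding).translate(table=11, cds=True))
            genomic = coding if plan.strand == "+" else revcomp(coding)
        else:
            genomic = "".join(_pick_base(rng, gc_target) for _ in range(plan.length))
            translation = None
        for j, base in enumerate(genomic):
            seq[start + j] = base
        alt_ids = (f"{gi_base + i}", f"SYP{acc_code:08x}{i + 1:04d}.1")
        feature = GeneFeature(
            primary_id=primary, start=start, end=end, strand=plan.strand,
            kind=plan.kind, alt_ids=alt_ids, trivial_name=plan.trivial_name,
            product=plan.product, cog_category=plan.cog,
            pfam_domains=plan.pfam, location_prediction=plan.location,
            translation=translation,
        )
        features.append(feature)
        manifest_features.append({
            "primary_id": primary, "alt_ids": list(alt_ids),
            "start": start, "end": end, "strand": plan.strand,
            "kind": plan.kind, "product": plan.product,
            "trivial_name": plan.trivial_name, "cog": plan.cog,
            "pfam": format_pfam_field(plan.pfam), "location": plan.location,
            "translation": translation, "role": plan.role,
        })
    for i in range(length):
        if seq[i] is None:
            seq[i] = _pick_base(rng, gc_target)
    sequence = _tune_gc(rng, seq, placements, length, gc_target)
    genome = GenomeRecord(accession=accession, length=length,
                          features=features, sequence=sequence,
                          topology=topology)
    manifest = {
        "accession": accession, "length": length, "topology": topology,
        "gc_target": gc_target, "features": manifest_features,
    }
    return genome, manifest


def hash_seed(text: str) -> int:
    import zlib
    return zlib.crc32(text.encode("utf-8"))


def _tune_gc(rng, seq, placements, length, gc_target):
    """Flip intergenic bases until genome GC is within 0.5 points of target."""
    genic = [False] * length
    for start, end in placements:
        for i in range(start, end):
            genic[i] = True
    intergenic = [i for i in range(length) if not genic[i]]
    rng.shuffle(intergenic)
    gc = sum(1 for b in seq if b in "GC")
    target = gc_target * length
    flip_to_gc = gc < target
    for i in intergenic:
        if abs(gc - target) <= 0.005 * length:
            break
        b = seq[i]
        if flip_to_gc and b in "AT":
            seq[i] = "G" if b == "A" else "C"
            gc += 1
        elif not flip_to_gc and b in "GC":
            seq[i] = "A" if b == "G" else "T"
            gc -= 1
    return "".join(seq)


def synth_genome(seed: int, n_genes: int = 20, length: int = 30000,
                 gc_target: float = 0.5, topology: str = "linear",
                 accession: str = None):
    """Generate one synthetic genome with known ground truth.

    Genes are non-overlapping, 300-2400 nt (multiples of 3), random
    strands, gaps >= 1 nt; coding strands start with ATG, end with a stop,
    and contain no internal stop; genome GC lands within the target.
    Returns ``(GenomeRecord, manifest)``.
    """
    if n_genes < 1:
        raise ContextmapError("n_genes must be >= 1")
    rng = random.Random(seed)
    accession = accession or f"SYN{seed % 100000:05d}"
    plans = _random_plan(rng, n_genes, length, gc_target)
    return _synthesize(rng, accession, plans, length, gc_target, topology)


# ---------------------------------------------------------------------------
# Conserved contexts across genomes + tree
# ---------------------------------------------------------------------------

DEFAULT_BLOCK = ("regulator", "transporter", "hydrolase", "kinase")

_ROLE_PRODUCTS = {
    "regulator": ("transcriptional regulator", "galR", "K"),
    "transporter": ("ABC transporter permease", None, "G"),
    "hydrolase": ("beta-galactosidase", "lacZ", "G"),
    "kinase": ("galactokinase", None, "G"),
    "pts": ("PTS system transporter subunit IIA", None, "G"),
    "synthetase": ("glutamine synthetase", "glnA", "E"),
}


def synth_conserved_contexts(seed: int, n_genomes: int = 8,
                             block=DEFAULT_BLOCK, divergence: float = 0.25,
                             n_background: int = 10, length: int = 30000,
                             gc_target: float = 0.45):
    """Generate genomes sharing a conserved gene block, plus a Newick tree.

    Each genome embeds the block (anchor = first role); with probability
    ``divergence`` per genome one perturbation is applied: loss of a random
    non-anchor role, insertion of a background gene inside the block, or a
    whole-block strand flip. Leaf labels embed the per-genome anchor
    identifier behind a ``|`` delimiter. Returns
    ``(genomes, manifest, newick_text)``.
    """
    if len(block) < 2:
        raise ContextmapError("conserved block needs at least 2 roles")
    rng = random.Random(seed)
    role_attrs = {}
    for role in block:
        product, trivial, cog = _ROLE_PRODUCTS.get(
            role, (rng.choice(PRODUCT_VOCAB), None, rng.choice(COG_LETTERS)))
        role_attrs[role] = {
            "product": product, "trivial": trivial, "cog": cog,
            "pfam": _random_pfam(rng),
            "length": 3 * rng.randint(MIN_GENE // 3, 500),
        }
    genomes = []
    per_genome = []
    for g in range(n_genomes):
        accession = f"SYNC{seed % 1000:03d}G{g:02d}"
        pre = rng.randint(3, n_background // 2 + 3)
        post = max(n_background - pre, 2)
        roles = list(block)
        flipped = False
        perturbation = None
        if rng.random() < divergence:
            perturbation = rng.choice(("loss", "insertion", "flip"))
            if perturbation == "loss" and len(roles) > 2:
                lost = rng.choice(roles[1:])
                roles.remove(lost)
            elif perturbation == "insertion":
                where = rng.randint(1, len(roles) - 1)
                roles.insert(where, None)       # None = background insert
            elif perturbation == "flip":
                flipped = True
        block_plans = []
        for role in roles:
            if role is None:
                block_plans.append(GenePlan(
                    length=3 * rng.randint(MIN_GENE // 3, 400),
                    strand="+", product=rng.choice(PRODUCT_VOCAB),
                    cog=rng.choice(COG_LETTERS), pfam=_random_pfam(rng),
                    location=rng.choice(LOCATION_VOCAB), role="insertion",
                ))
            else:
                attrs = role_attrs[role]
                block_plans.append(GenePlan(
                    length=attrs["length"], strand="+",
                    product=attrs["product"], trivial_name=attrs["trivial"],
                    cog=attrs["cog"], pfam=attrs["pfam"],
                    location="cytoplasmic", role=role,
                ))
        if flipped:
            block_plans = list(reversed(block_plans))
            for p in block_plans:
                p.strand = "-"
        plans = (_random_plan(rng, pre, length, gc_target) + block_plans
                 + _random_plan(rng, post, length, gc_target))
        genome, manifest = _synthesize(rng, accession, plans, length,
                                       gc_target, "linear")
        roles_present = {}
        anchor_id = None
        for mf in manifest["features"]:
            if mf["role"] and mf["role"] != "insertion":
                roles_present[mf["role"]] = mf["primary_id"]
                if mf["role"] == block[0]:
                    anchor_id = mf["primary_id"]
        per_genome.append({
            "accession": accession, "anchor_id": anchor_id,
            "roles_present": roles_present, "block_flipped": flipped,
            "perturbation": perturbation, "manifest": manifest,
        })
        genomes.append(genome)
    newick = _random_newick(rng, per_genome)
    manifest = {"seed": seed, "block": list(block),
                "divergence": divergence, "genomes": per_genome,
                "newick": newick}
    return genomes, manifest, newick


def _random_newick(rng, per_genome) -> str:
    """Random binary tree whose leaf labels embed the anchor identifiers
    behind a '|' delimiter."""
    nodes = [f"g{i}|{pg['anchor_id']}:{rng.uniform(0.05, 1.0):.3f}"
             for i, pg in enumerate(per_genome)]
    if len(nodes) == 1:
        return nodes[0].rsplit(":", 1)[0] + ";"
    while len(nodes) > 2:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.3f}")
    return f"({nodes[0]},{nodes[1]});"


# ---------------------------------------------------------------------------
# Overlay fixtures
# ---------------------------------------------------------------------------


def synth_overlays(seed: int, genomes, context_manifest,
                   site_fraction: float = 0.6,
                   score_range=(70.0, 100.0)):
    """Plant scored binding sites upstream of a fraction of anchors and
    assign correlated expression ratios.

    Site-bearing anchors draw ratios from a down-regulated band
    (-3.0..-1.5), others sit near zero (-0.3..0.3), and one siteless decoy
    anchor gets the strongest response (-4.0..-3.5), mimicking an
    indirectly regulated operon. Returns
    ``(element_tsv, quant_tsv, ground_truth)`` with TSV coordinates
    1-based inclusive.
    """
    rng = random.Random(seed)
    by_acc = {g.accession: g for g in genomes}
    anchors = []
    for pg in context_manifest["genomes"]:
        genome = by_acc[pg["accession"]]
        feature = next(f for f in genome.features
                       if f.primary_id == pg["anchor_id"])
        anchors.append((pg["accession"], feature))
    n_sites = round(site_fraction * len(anchors))
    site_idx = set(rng.sample(range(len(anchors)), n_sites))
    no_site = [i for i in range(len(anchors)) if i not in site_idx]
    decoy_idx = rng.choice(no_site) if no_site else None

    element_lines = []
    quant_lines = []
    truth = []
    for i, (accession, feature) in enumerate(anchors):
        entry = {"accession": accession, "anchor_id": feature.primary_id,
                 "has_site": i in site_idx, "is_decoy": i == decoy_idx}
        if i in site_idx:
            offset = rng.randint(40, 70)
            size = rng.randint(14, 22)
            if feature.strand == "+":
                start = feature.start - offset - size
                end = feature.start - offset
            else:
                start = feature.end + offset
                end = feature.end + offset + size
            score = round(rng.uniform(*score_range), 2)
            label = f"site_{feature.primary_id}"
            element_lines.append(
                f"{accession}\t{start + 1}\t{end}\t{feature.strand}\t{score}\t{label}"
            )
            entry.update(site_start=start, site_end=end,
                         site_strand=feature.strand, score=score, label=label)
            ratio = round(rng.uniform(-3.0, -1.5), 3)
        elif i == decoy_idx:
            ratio = round(rng.uniform(-4.0, -3.5), 3)
        else:
            ratio = round(rng.uniform(-0.3, 0.3), 3)
        entry["ratio"] = ratio
        quant_lines.append(f"{feature.primary_id}\t{ratio}")
        truth.append(entry)
    element_tsv = "\n".join(element_lines) + ("\n" if element_lines else "")
    quant_tsv = "gene\tratio\n" + "\n".join(quant_lines) + "\n"
    return element_tsv, quant_tsv, truth


# ---------------------------------------------------------------------------
# Writers (GenBank / GFF3+FASTA) so reader equivalence is testable
# ---------------------------------------------------------------------------

_GB_DATE = "01-JAN-2020"   # fixed so GenBank output is byte-stable


def write_genbank(genome: GenomeRecord, path):
    """Serialize a GenomeRecord as a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence or "N" * genome.length),
        id=genome.accession, name=genome.accession[:16],
        description="synthetic genome",
        annotations={
            "molecule_type": "DNA", "topology": genome.topology,
            "data_file_division": "BCT", "date": _GB_DATE,
            "accessions": [genome.accession],
        },
    )
    for f in genome.features:
        quals = {"locus_tag": [f.primary_id]}
        if f.trivial_name:
            quals["gene"] = [f.trivial_name]
        if f.product:
            quals["product"] = [f.product]
        if f.alt_ids:
            quals["protein_id"] = [f.alt_ids[1]] if len(f.alt_ids) > 1 else []
            quals["db_xref"] = [f"GI:{f.alt_ids[0]}"]
        if f.cog_category:
            quals["cog_category"] = [f.cog_category]
        if f.pfam_domains:
            quals["pfam_domains"] = [format_pfam_field(f.pfam_domains)]
        if f.location_prediction:
            quals["sub_location"] = [f.location_prediction]
        if f.translation:
            quals["translation"] = [f.translation]
        quals = {k: v for k, v in quals.items() if v}
        record.features.append(SeqFeature(
            FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
            type=f.kind, qualifiers=quals,
        ))
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


def _gff_escape(value: str) -> str:
    return (value.replace("%", "%25").replace(";", "%3B")
            .replace("=", "%3D").replace("&", "%26").replace(",", "%2C"))


def write_gff3(genome: GenomeRecord, path, embed_fasta: bool = True,
               fasta_path=None):
    """Serialize a GenomeRecord as GFF3, with the sequence embedded under
    ``##FASTA`` or written to a separate FASTA file."""
    lines = ["##gff-version 3",
             f"##sequence-region {genome.accession} 1 {genome.length}"]
    if genome.topology == "circular":
        lines.append(f"{genome.accession}\tcontextmap\tregion\t1\t{genome.length}"
                     f"\t.\t+\t.\tID=region0;Is_circular=true")
    for f in genome.features:
        attrs = [f"ID={_gff_escape(f.primary_id)}",
                 f"locus_tag={_gff_escape(f.primary_id)}"]
        if f.trivial_name:
            attrs.append(f"Name={_gff_escape(f.trivial_name)}")
        if f.product:
            attrs.append(f"product={_gff_escape(f.product)}")
        if f.alt_ids:
            if len(f.alt_ids) > 1:
                attrs.append(f"protein_id={_gff_escape(f.alt_ids[1])}")
            attrs.append(f"Dbxref=GI:{_gff_escape(f.alt_ids[0])}")
        if f.cog_category:
            attrs.append(f"cog_category={_gff_escape(f.cog_category)}")
        if f.pfam_domains:
            attrs.append(f"pfam_domains={_gff_escape(format_pfam_field(f.pfam_domains))}")
        if f.location_prediction:
            attrs.append(f"sub_location={_gff_escape(f.location_prediction)}")
        if f.translation:
            attrs.append(f"translation={_gff_escape(f.translation)}")
        phase = "0" if f.kind == "CDS" else "."
        lines.append(f"{genome.accession}\tcontextmap\t{f.kind}\t{f.start + 1}"
                     f"\t{f.end}\t.\t{f.strand}\t{phase}\t" + ";".join(attrs))
    text = "\n".join(lines) + "\n"
    if genome.sequence is not None:
        fasta = f">{genome.accession}\n" + "\n".join(
            genome.sequence[i:i + 70] for i in range(0, genome.length, 70)) + "\n"
        if embed_fasta:
            text += "##FASTA\n" + fasta
        elif fasta_path is not None:
            with open(fasta_path, "w") as fh:
                fh.write(fasta)
    with open(path, "w") as fh:
        fh.write(text)
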