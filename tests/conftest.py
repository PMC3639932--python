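import random

import pytest

from contextmap import fixtures as fx


@pytest.fixture(scope="session")
def small_genome():
    """One deterministic 15-gene genome plus its manifest."""
    return fx.synth_genome(seed=11, n_genes=15, length=25000, gc_target=0.5)


@pytest.fixture(scope="session")
def genome_set():
    """Three deterministic genomes with disjoint accessions."""
    out = []
    for s in (21, 22, 23):
        g, m = fx.synth_genome(seed=s, n_genes=12, length=20000,
                               accession=f"SETG{s:02d}")
        out.append((g, m))
    return out


@pytest.fixture(scope="session")
def conserved_set():
    """Conserved-context genomes, manifest and tree (seeded)."""
    genomes, manifest, newick = fx.synth_conserved_contexts(
        seed=7, n_genomes=6, divergence=0.3)
    return genomes, manifest, newick


@pytest.fixture()
def rng():
    return random.Random(1234)
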