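import numpy as np
import pytest

import integscape as ig
from integscape.genomic_core import Genome, GenomicInterval, IntegrationSite


@pytest.fixture(scope="session")
def small_genome():
    """200-kb single-chromosome random genome for module-level tests."""
    return ig.make_genome(200_000, gc_fraction=0.4, seed=101)


@pytest.fixture(scope="session")
def small_annotation(small_genome):
    genes, tracks = ig.make_gene_models(small_genome, n_genes=10, seed=102)
    return genes, tracks


def make_site(chrom, pos, strand="+", vector="Ds", count=100, method="NGS",
              length=1):
    return IntegrationSite(
        GenomicInterval(chrom, pos, pos + length, strand),
        vector=vector, fragment_count=count, method=method,
    )


@pytest.fixture
def plain_genome():
    """All-A 200-bp chromosome: contains no restriction motifs until planted."""
    return Genome({"c1": "A" * 200})


def plant(genome: Genome, chrom: str, pos: int, motif: str) -> Genome:
    seq = genome.sequences[chrom]
    return Genome({
        **genome.sequences,
        chrom: seq[:pos] + motif + seq[pos + len(motif):],
    })
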