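import pytest

from bivalent_smad.genome_io import Annotation, GeneModel, GenomicInterval
from bivalent_smad.synthetic_data import SimConfig, simulate_dataset


def make_gene(gene_id, chrom, start, blocks, strand):
    """GeneModel from (offset, length) exon blocks relative to ``start``."""
    exons = tuple(
        GenomicInterval(chrom, start + off, start + off + ln, strand)
        for off, ln in blocks
    )
    end = max(e.end for e in exons)
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                     exons)


@pytest.fixture
def tiny_annotation():
    """Three genes on two chromosomes, both strands, known introns."""
    genes = {
        "gA": make_gene("gA", "chr1", 1_000, [(0, 100), (200, 100)], "+"),
        "gB": make_gene("gB", "chr1", 10_000, [(0, 500), (900, 300),
                                               (1500, 200)], "-"),
        "gC": make_gene("gC", "chr2", 5_000, [(0, 800)], "+"),
    }
    return Annotation(genes, {"chr1": 50_000, "chr2": 20_000})


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated study (seed 7), shared across test modules."""
    return simulate_dataset(SimConfig(seed=7))
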