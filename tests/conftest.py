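import pytest

from histmark.core import GeneModel, GenomicInterval
from histmark.genome_partition import RegionClass
from histmark.synthetic_data import me3_like, simulate_mark


def make_gene(
    transcript_id,
    chrom,
    strand,
    tx_start,
    tx_end,
    exons=None,
    symbols=None,
):
    """Gene model helper; exons default to a single block spanning the body."""
    if exons is None:
        exons = [(tx_start, tx_end)]
    return GeneModel(
        transcript_id=transcript_id,
        gene_symbols=tuple(symbols or (transcript_id,)),
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


@pytest.fixture
def toy_genome():
    """A 100 kb chromosome with two multi-exon genes on opposite strands."""
    sizes = {"chrT": 100_000}
    genes = [
        make_gene(
            "tx1", "chrT", "+", 10_000, 20_000,
            exons=[(10_000, 11_000), (14_000, 15_000), (19_000, 20_000)],
            symbols=("GENE1",),
        ),
        make_gene(
            "tx2", "chrT", "-", 40_000, 55_000,
            exons=[(40_000, 42_000), (50_000, 55_000)],
            symbols=("GENE2",),
        ),
    ]
    return sizes, genes


def brute_force_base_class(genes, halfwidth, pos, strand_aware=True):
    """Per-base oracle for the four-class partition (precedence rule)."""
    for g in genes:
        tss = g.tss(strand_aware=strand_aware)
        if halfwidth > 0 and tss - halfwidth <= pos < tss + halfwidth:
            return RegionClass.PROXIMAL_PROMOTER
    for g in genes:
        for e in g.exons:
            if e.start <= pos < e.end:
                return RegionClass.EXON
    for g in genes:
        if g.tx_start <= pos < g.tx_end:
            return RegionClass.INTRON
    return RegionClass.INTERGENIC


@pytest.fixture(scope="session")
def small_simulation():
    """A compact me3-like simulation shared across tests (fixed seed)."""
    params = me3_like(
        seed=11,
        n_genes=40,
        library_size=30_000,
        n_peaks_per_mark=80,
        chrom_lengths={"chrS1": 3_000_000},
    )
    genome, truth, tags_a, tags_b = simulate_mark(params)
    return params, genome, truth, tags_a, tags_b
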