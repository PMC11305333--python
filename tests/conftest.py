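import pytest

from convloss import simulate


@pytest.fixture(scope="session")
def small_genome_annotation():
    """A 2-chromosome genome with 12 genes on both strands."""
    genome = simulate.gen_genome(2, 200_000, seed=11)
    annotation = simulate.gen_gene_models(
        genome,
        n_genes=12,
        exon_count_range=(2, 6),
        exon_len_range=(120, 360),
        intron_len_range=(60, 300),
        seed=12,
    )
    return genome, annotation


@pytest.fixture(scope="session")
def big_exon_gene():
    """A genome holding genes with exons large enough for a 474-bp deletion."""
    genome = simulate.gen_genome(1, 100_000, seed=21)
    annotation = simulate.gen_gene_models(
        genome,
        n_genes=3,
        exon_count_range=(6, 7),
        exon_len_range=(500, 700),
        intron_len_range=(60, 200),
        seed=22,
    )
    return genome, annotation
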