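import pytest

from codoncontext import (
    CodingSequence,
    SyntheticGenomeSpec,
    build_context_matrix,
    random_context_matrix,
    sample_genome,
)


@pytest.fixture(scope="session")
def met_cys_matrix():
    """Context matrix in which 60% of observed Met-Cys pairs are ATGTGT
    and 40% are ATGTGC (built from counts 3 and 2)."""
    genes = [CodingSequence(f"g{i}", "ATGTGT") for i in range(3)] + [
        CodingSequence(f"h{i}", "ATGTGC") for i in range(2)
    ]
    return build_context_matrix(genes, source_label="met-cys-60-40")


@pytest.fixture(scope="session")
def generator_matrix():
    return random_context_matrix(seed=11, source_label="generator")


@pytest.fixture(scope="session")
def small_genome(generator_matrix):
    """120 genes x 60 codons sampled from a known generator."""
    spec = SyntheticGenomeSpec(
        n_genes=120, codons_per_gene=60, generator_matrix=generator_matrix, seed=5
    )
    genes, _ = sample_genome(spec)
    return genes


@pytest.fixture(scope="session")
def small_genome_matrix(small_genome):
    return build_context_matrix(small_genome, source_label="small-genome")
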