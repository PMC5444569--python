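import pytest

from genoparts import (
    GeneratorSpec,
    compile_dataset,
    make_dataset,
    make_edge_cases,
)

EDGE_SEED = 11
DATASET_SEED = 7
PROPERTY_SEED = 23


@pytest.fixture(scope="session")
def edge_bundle():
    return make_edge_cases(EDGE_SEED)


@pytest.fixture(scope="session")
def edge_result(edge_bundle):
    b = edge_bundle
    return compile_dataset(
        b.genome, b.transcripts, b.mappings,
        blast_hits=b.blast_hits, pfam_hits=b.pfam_hits,
    )


@pytest.fixture(scope="session")
def dataset_bundle():
    return make_dataset(DATASET_SEED)


@pytest.fixture(scope="session")
def dataset_result(dataset_bundle):
    b = dataset_bundle
    return compile_dataset(
        b.genome, b.transcripts, b.mappings,
        blast_hits=b.blast_hits, pfam_hits=b.pfam_hits,
    )


@pytest.fixture(scope="session")
def big_result():
    """≥100 random fixture genes for the property suites."""
    b = make_dataset(PROPERTY_SEED, GeneratorSpec(n_loci=70, loci_per_contig=5))
    return compile_dataset(
        b.genome, b.transcripts, b.mappings,
        blast_hits=b.blast_hits, pfam_hits=b.pfam_hits,
    )


def locus_of(result, gene):
    return next(l for l in result.loci if l.locus_id == gene.locus_id)
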