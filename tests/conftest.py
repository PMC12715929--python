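import pytest

from locus_colocal.annotation_io import ContigAnnotation, GeneFeature
from locus_colocal.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 50-test / 100-control corpus with the default planted structure."""
    from locus_colocal.synthetic import default_spec

    spec = default_spec(n_test=50, n_control=100, vocab_size=500)
    return generate_corpus(spec, seed=42)


@pytest.fixture(scope="session")
def null_corpus():
    """No planted enrichment: test and control share one background law."""
    spec = SyntheticSpec(n_test=150, n_control=300, vocab_size=800)
    return generate_corpus(spec, seed=7)


@pytest.fixture
def toy_contig():
    """Hand-built contig: five genes on a 100 kb contig."""
    genes = [
        GeneFeature("CTG1", 1_000, 2_000, "+", "g1", "a", ["PF00001"]),
        GeneFeature("CTG1", 30_000, 31_000, "-", "g2", "b", ["PF00002"]),
        GeneFeature("CTG1", 50_000, 52_000, "+", "anchor", "anchor", ["PF05147"]),
        GeneFeature("CTG1", 70_990, 71_010, "+", "g4", "c", ["PF00003"]),
        GeneFeature("CTG1", 90_000, 91_000, "-", "g5", "d", []),
    ]
    return ContigAnnotation(contig_id="CTG1", features=genes, length=100_000)
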