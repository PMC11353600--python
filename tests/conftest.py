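import pytest

from utrsurvey.annotation import parse_annotation
from utrsurvey.simulate import GeneratorParams, generate_annotation

# One + strand gene: exons 101-200 and 301-400 (1-based), CDS 151-200 and
# 301-350.  Exonic length 200, CDS 100, five_len 50 (101-150), three_len 50
# (351-400).
TWO_EXON_GTF = "\n".join(
    [
        "\t".join(["chr1", "t", "exon", "101", "200", ".", "+", ".",
                   'gene_id "g1"; transcript_id "g1.t1";']),
        "\t".join(["chr1", "t", "exon", "301", "400", ".", "+", ".",
                   'gene_id "g1"; transcript_id "g1.t1";']),
        "\t".join(["chr1", "t", "CDS", "151", "200", ".", "+", ".",
                   'gene_id "g1"; transcript_id "g1.t1";']),
        "\t".join(["chr1", "t", "CDS", "301", "350", ".", "+", ".",
                   'gene_id "g1"; transcript_id "g1.t1";']),
    ]
) + "\n"


@pytest.fixture
def two_exon_gtf() -> str:
    return TWO_EXON_GTF


@pytest.fixture
def two_exon_annotation():
    return parse_annotation(TWO_EXON_GTF)


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-gene synthetic fixture shared across tests."""
    return generate_annotation(GeneratorParams(n_genes=200, seed=11))


@pytest.fixture(scope="session")
def small_bundle_noseq():
    return generate_annotation(
        GeneratorParams(n_genes=300, seed=12), with_sequences=False
    )
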