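import numpy as np
import pytest

from riboclip.reference import Genome, OrfAnnotation


@pytest.fixture
def toy_genome():
    """1 chromosome holding a 5-codon + strand gene and a 5-codon - strand gene.

    plus gene: ATG AAA CCC GGG TAA at [10, 25)
    minus gene: spliced 'ATGTTTACAGCGTAA' encoded as reverse complement
    at [40, 55).
    """
    plus_cds = "ATGAAACCCGGGTAA"
    minus_spliced = "ATGTTTACAGCGTAA"
    comp = str.maketrans("ACGT", "TGCA")
    minus_cds = minus_spliced.translate(comp)[::-1]
    seq = "T" * 10 + plus_cds + "A" * 15 + minus_cds + "C" * 15
    return Genome({"chr1": seq})


@pytest.fixture
def toy_genes():
    return [
        OrfAnnotation("plus_gene", "chr1", "+", 10, 25),
        OrfAnnotation("minus_gene", "chr1", "-", 40, 55),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
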