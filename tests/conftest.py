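import numpy as np
import pytest

from selfsel.genetic_code import STANDARD_CODE
from selfsel.io import CodonAlignment, GenotypeSequence


def make_alignment(seqs: dict[str, str], outgroup: str = "out", locus: str = "L1") -> CodonAlignment:
    """Build a CodonAlignment from genotype -> nucleotide strings."""
    gs = {g: GenotypeSequence.from_nucleotides(g, s) for g, s in seqs.items()}
    return CodonAlignment(locus, gs, outgroup)


@pytest.fixture
def code():
    return STANDARD_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sense_codon(rng, code=STANDARD_CODE) -> str:
    codons = code.sense_codons
    return codons[rng.integers(len(codons))]


def random_gene(rng, n_codons: int, code=STANDARD_CODE) -> str:
    return "".join(random_sense_codon(rng, code) for _ in range(n_codons))
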