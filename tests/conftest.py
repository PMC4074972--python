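import numpy as np
import pytest

from wavedist import GeneratorSpec, identity_matrix, random_sequences, read_substitution_matrix

DNA = "ACGT"
AMINO = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def dna_identity():
    """+1/-1 match/mismatch over {A,C,G,T} with linear gap score -2."""
    return identity_matrix(DNA, gap=-2)


@pytest.fixture(scope="session")
def blosum62():
    return read_substitution_matrix("blosum62", gap=-10)


@pytest.fixture
def small_set():
    """Six seeded random DNA sequences of length 30."""
    return random_sequences(GeneratorSpec(alphabet=DNA, n=6, length=30, seed=11))


def random_pair(rng, alphabet=DNA, max_len=60):
    """One random sequence pair with independent lengths in 1..max_len."""
    l1, l2 = rng.integers(1, max_len + 1, size=2)
    pick = lambda k: "".join(rng.choice(list(alphabet), size=k))
    return pick(l1), pick(l2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
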