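import numpy as np
import pytest

from pathpack.sequence import NUCLEOTIDES


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, n))
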