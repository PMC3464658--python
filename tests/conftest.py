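import numpy as np
import pytest

from tandemdup.seqio import GenomeSequence

from .helpers import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def random_sequence(rng):
    return GenomeSequence("rand", random_dna(rng, 10_000))
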