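import numpy as np
import pytest

from structatlas.fixtures import random_dna
from structatlas.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_703)


@pytest.fixture
def random_seq(rng):
    def make(length: int, seq_id: str = "rand") -> SequenceRecord:
        return SequenceRecord(id=seq_id, seq=random_dna(length, rng))
    return make
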