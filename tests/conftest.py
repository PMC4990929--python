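import random

import pytest

from cblscreen.seq_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture
def rng():
    return random.Random(20_230_901)


def random_protein(rng: random.Random, length: int, rec_id: str = "p",
                   species: str = "unknown") -> ProteinRecord:
    seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
    return ProteinRecord(id=rec_id, sequence=seq, species=species)
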