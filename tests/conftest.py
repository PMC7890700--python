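import random

import pytest

from starmsa import ScoringScheme, worked_example

BASES = "ACGT"


@pytest.fixture
def default_scheme():
    return ScoringScheme()


@pytest.fixture
def demo_seqs():
    return worked_example()


def random_dna(rng: random.Random, max_len: int, min_len: int = 0) -> str:
    return "".join(rng.choice(BASES) for _ in range(rng.randint(min_len, max_len)))
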