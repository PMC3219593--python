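from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from recoil.encoder import MemMatch
from recoil.sequence import Read

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the three-read toy dataset: ids follow input order, the encoding tree joins
#: read 0 to read 2 and read 2 to read 1, rooted at read 0
TOY_READS = [Read(0, "ACCGTTA"), Read(1, "CCCTTAG"), Read(2, "GTTAGCA")]
TOY_TREE_EDGES = [(0, 2, 5, 0), (1, 2, 3, 0)]
TOY_BFS_ORDER = [0, 2, 1]


@pytest.fixture
def toy_reads() -> list[Read]:
    return list(TOY_READS)


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0xC0FFEE)


def random_mems(rng: random.Random, n: int, span: int = 200, max_len: int = 30) -> list[MemMatch]:
    return [
        MemMatch(rng.randrange(span), rng.randrange(span), rng.randint(1, max_len))
        for _ in range(n)
    ]
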