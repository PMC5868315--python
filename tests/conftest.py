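import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from g4logic.core import Domain, Role, Strand

ALL_CIRCUITS = (
    "XOR", "OR", "AND", "XNOR", "NAND", "NOR", "INHIBIT", "IMPLICATION",
    "XOR_AND", "XOR_NOR",
)

#: gates whose Boolean function is symmetric in the two inputs
SYMMETRIC_CIRCUITS = ("XOR", "OR", "AND", "XOR_AND", "XOR_NOR")


def random_domain(rng: random.Random, names="abcd",
                  lengths=(4, 6, 8, 12)) -> Domain:
    return Domain(
        name=rng.choice(names),
        length=rng.choice(lengths),
        starred=rng.random() < 0.5,
        role=rng.choice(list(Role)),
    )


def random_strand(rng: random.Random, name: str, max_domains: int = 4) -> Strand:
    n = rng.randint(1, max_domains)
    return Strand(name, tuple(random_domain(rng) for _ in range(n)))


@pytest.fixture
def rng():
    return random.Random(0)
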