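import random

import pytest
from hypothesis import settings

from oxocello import (
    C6State,
    DEFAULT_LIBRARY,
    Oligosaccharide,
    OxidationState,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return DEFAULT_LIBRARY


def random_oligo(rng: random.Random, max_dp: int = 6) -> Oligosaccharide:
    """A random structurally legal oxidized chain (shared helper)."""
    dp = rng.randint(1, max_dp)
    residues = []
    for i in range(dp):
        c1 = i == dp - 1 and rng.random() < 0.3
        c4 = rng.random() < 0.2
        c6 = rng.choice([C6State.NONE, C6State.NONE, C6State.ALDEHYDE, C6State.ACID])
        max_lact = int(c1) + int(c6 == C6State.ACID)
        lact = rng.randint(0, max_lact)
        u = i == 0 and dp > 1 and rng.random() < 0.1 and not c1
        residues.append(OxidationState(c1, c4, c6, lact, u))
    return Oligosaccharide(tuple(residues))
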