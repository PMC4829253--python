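import random

import pytest

from cissers.enzyme_db import IUPAC_SETS, Enzyme, load_bundled_enzymes
from cissers.fixtures import make_polyT_probe


@pytest.fixture(scope="session")
def bundled_db():
    return load_bundled_enzymes()


@pytest.fixture
def ecori():
    return Enzyme(name="EcoRI", site="GAATTC", cut_offset_top=1)


@pytest.fixture
def taqi():
    return Enzyme(name="TaqI", site="TCGA", cut_offset_top=1)


@pytest.fixture
def probe_60():
    """The classic validation construct: 27 T + GAATTC + 27 T."""
    return make_polyT_probe("GAATTC", 60)


def brute_force_scan(seq, pattern, overlap_mode):
    """Position-by-position reference matcher, independent of the regex
    path: subset semantics, explicit resume rule."""
    starts = []
    i = 0
    n, k = len(seq), pattern.length
    while i <= n - k:
        hit = all(
            IUPAC_SETS.get(seq[i + j], frozenset()) <= pattern.allowed[j]
            for j in range(k)
        )
        if hit:
            starts.append(i)
            i += k if overlap_mode == "non_overlapping" else 1
        else:
            i += 1
    return starts


@pytest.fixture(scope="session")
def oracle_scan():
    return brute_force_scan


def random_iupac(rng: random.Random, length: int, degenerate_bias: float = 0.3) -> str:
    letters = list(IUPAC_SETS)
    concrete = list("ACGT")
    return "".join(
        rng.choice(letters) if rng.random() < degenerate_bias else rng.choice(concrete)
        for _ in range(length)
    )


@pytest.fixture(scope="session")
def make_random_iupac():
    return random_iupac
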