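"""Shared fixtures: random valid genotype tables and small enumerable spaces."""

import numpy as np
import pytest

from dpgwas import GenotypeTable, TableSpace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140308)


def random_polymorphic_table(rng, max_n=60):
    """A random genotype table with positive allelic margins on both columns."""
    while True:
        R = int(rng.integers(2, max_n))
        S = int(rng.integers(2, max_n))
        r = rng.multinomial(R, np.full(3, 1 / 3))
        s = rng.multinomial(S, np.full(3, 1 / 3))
        t = GenotypeTable(*r, *s)
        a = 2 * (r[0] + s[0]) + r[1] + s[1]
        if 0 < a < 2 * t.N:
            return t


@pytest.fixture(scope="session")
def random_tables(rng):
    """1000 random polymorphic tables reused across equivalence tests."""
    return [random_polymorphic_table(rng) for _ in range(1000)]


@pytest.fixture(scope="session")
def small_space():
    return TableSpace(40, 40, 20, 10)
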