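import numpy as np
import pytest

from clonesim import CloneSizeTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    return CloneSizeTable(["a", "b", "c", "d"], [1, 2, 3, 4])


def brute_force_gini(sizes, c0=None):
    """Independent O(C0^2) oracle for the Gini coefficient."""
    sizes = list(sizes)
    if c0 is None:
        c0 = len(sizes)
    assert len(sizes) == c0
    n = sum(sizes)
    total = 0.0
    for a in sizes:
        for b in sizes:
            total += abs(a - b)
    return total / (2.0 * c0 * n)


def exact_ssa_birth(sizes, r, t_end, rng):
    """Direct-method (first-principles) birth process oracle.

    Exponential waiting times at total rate r * n; the dividing clone is
    chosen proportionally to its size.  Returns final sizes at t_end.
    """
    sizes = np.array(sizes, dtype=np.int64)
    t = 0.0
    n = int(sizes.sum())
    while True:
        rate = r * n
        t += rng.exponential(1.0 / rate)
        if t > t_end:
            return sizes
        i = rng.choice(sizes.size, p=sizes / n)
        sizes[i] += 1
        n += 1
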