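import itertools

import numpy as np
import pytest

from crossmatch.matching import MatchWindow
from crossmatch.stimulus import StereoPair


@pytest.fixture
def rng():
    return np.random.default_rng(20140127)


def ternary_rows(k):
    """All ternary row images of length k, as (3^k, k) int8 arrays."""
    return np.array(list(itertools.product((-1, 0, 1), repeat=k)), dtype=np.int8)


def row_pair(left_row, right_row):
    """A 1-row StereoPair from two equal-length ternary vectors."""
    return StereoPair(
        np.asarray(left_row, dtype=np.int8)[None, :],
        np.asarray(right_row, dtype=np.int8)[None, :],
    )


def full_row_window(k, d=0):
    return MatchWindow(np.zeros(k, dtype=int), np.arange(k), d)


def brute_force_operators(left_row, right_row):
    """Reference pixel-by-pixel evaluation of all four operators (d=0).

    Deliberately scalar and loop-based, independent of the vectorized path.
    """
    k = len(left_row)
    products = [int(left_row[i]) * int(right_row[i]) for i in range(k)]
    corr = sum(products) / k
    match = sum(p for p in products if p > 0) / k
    gen = max(corr, 0.0)
    onoff = (
        sum(
            max(int(l), 0) * max(int(r), 0) + max(-int(l), 0) * max(-int(r), 0)
            for l, r in zip(left_row, right_row)
        )
        / k
    )
    return corr, match, gen, onoff
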