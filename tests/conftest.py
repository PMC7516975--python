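"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive lattice semantics from first
principles (explicit Python sets, full triple enumeration) so that the
package's optimized implementations are checked against something that
cannot share their bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

from ucurve import GroundSet, cost_gt


@pytest.fixture
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)
    return make


@pytest.fixture
def scrambled_ground():
    """A ground set given out of order, {c, b, e, d, a}, to exercise the
    lexicographic sorting of the encoding."""
    return GroundSet(["c", "b", "e", "d", "a"])


def enumerate_subsets(n: int):
    return range(1 << n)


def naive_u_decomposable_all_triples(costs, n: int) -> bool:
    """Check c(X2) <= max(c(X1), c(X3)) over ALL chain triples X1 ⊆ X2 ⊆ X3,
    not only consecutive-cardinality ones (O(8^n); n <= 6)."""
    for x2 in range(1 << n):
        for x1 in range(1 << n):
            if x1 & x2 != x1:
                continue
            for x3 in range(1 << n):
                if x2 & x3 != x2:
                    continue
                if cost_gt(costs[x2], max(costs[x1], costs[x3])):
                    return False
    return True


def naive_count_oscillations(costs, n: int) -> int:
    """Count consecutive-cardinality chain-triple violations by scanning all
    (X1, X2, X3) combinations (O(8^n); n <= 6)."""
    count = 0
    for x2 in range(1 << n):
        k2 = bin(x2).count("1")
        for x1 in range(1 << n):
            if x1 & x2 != x1 or bin(x1).count("1") != k2 - 1:
                continue
            for x3 in range(1 << n):
                if x2 & x3 != x2 or bin(x3).count("1") != k2 + 1:
                    continue
                if cost_gt(costs[x2], max(costs[x1], costs[x3])):
                    count += 1
    return count


class ExplicitSetStore:
    """Reference implementation of the subset-family store: a plain set."""

    def __init__(self, dimension: int):
        if dimension < 0:
            raise ValueError("negative dimension")
        self.dimension = dimension
        self.words = set(range(1 << dimension))

    def remove_interval(self, lower: int, upper: int) -> None:
        self.words = {
            w for w in self.words
            if not (lower & w == lower and w & upper == w)
        }

    def discard(self, word: int) -> None:
        self.words.discard(word)

    def contains(self, word: int) -> bool:
        return word in self.words

    def is_empty(self) -> bool:
        return not self.words

    def __len__(self) -> int:
        return len(self.words)

    def to_set(self) -> set:
        return set(self.words)


def random_interval(dim: int, rng: np.random.Generator):
    """A random valid interval [lower, upper] of width ``dim``."""
    upper = int(rng.integers(1 << dim)) if dim else 0
    lower = upper & (int(rng.integers(1 << dim)) if dim else 0)
    return lower, upper
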