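"""Compressed store of a family of outer-lattice elements.

The walk over the outer Boolean lattice starts from the *full* family
P(S′) — 2^|S′| bit words — so the store must not materialize its members.
Semantics are always those of an explicit set of fixed-width words; the
realization is an ROBDD, where removing the interval [lower, upper] is a
conjunction with the negated interval cube.
"""

from __future__ import annotations

from .bdd import BDD, FALSE, TRUE


class SubsetFamilyStore:
    """A family of bit words of width ``dimension`` with interval removal.

    Supports membership, emptiness, exact cardinality, removal of whole
    lattice intervals and seeded random extraction of one member.
    """

    def __init__(self, dimension: int, _bdd: BDD | None = None, _root: int | None = None):
        if dimension < 0:
            raise ValueError("store dimension must be non-negative")
        self.dimension = int(dimension)
        self._bdd = _bdd if _bdd is not None else BDD(self.dimension)
        self._root = _root if _root is not None else TRUE

    @classmethod
    def full(cls, dimension: int) -> "SubsetFamilyStore":
        """The full family of all 2^dimension words, held implicitly."""
        return cls(dimension)

    @classmethod
    def empty(cls, dimension: int) -> "SubsetFamilyStore":
        store = cls(dimension)
        store._root = FALSE
        return store

    def _check_word(self, word: int) -> None:
        if not 0 <= word < (1 << self.dimension):
            raise ValueError(
                f"word {word:#x} does not fit the store width {self.dimension}"
            )

    def _interval_literals(self, lower: int, upper: int):
        # membership in [lower, upper]: bit i forced 1 where lower has 1,
        # forced 0 where upper has 0; other bits free.
        lits = []
        for i in range(self.dimension):
            if lower >> i & 1:
                lits.append((i, 1))
            elif not (upper >> i & 1):
                lits.append((i, 0))
        return lits

    def remove_interval(self, lower: int, upper: int) -> None:
        """Delete every word w with lower ⊆ w ⊆ upper (bitwise containment)."""
        self._check_word(lower)
        self._check_word(upper)
        if lower & ~upper:
            raise ValueError("interval lower bound is not a subset of the upper bound")
        lits = self._interval_literals(lower, upper)
        self._root = self._bdd.conj(self._root, self._bdd.neg_cube(lits))

    def discard(self, word: int) -> None:
        """Remove a single word (no-op if absent)."""
        self.remove_interval(word, word)

    def contains(self, word: int) -> bool:
        self._check_word(word)
        return self._bdd.member(self._root, word)

    def is_empty(self) -> bool:
        return self._root == FALSE

    def __len__(self) -> int:
        return self._bdd.count(self._root)

    def pop(self, rng) -> int:
        """Remove and return one member, chosen uniformly by the seeded
        generator; raises ``KeyError`` when the store is empty (the
        walk-loop exit signal)."""
        if self.is_empty():
            raise KeyError("pop from an empty subset-family store")
        word = self._bdd.sample(self._root, rng)
        self.discard(word)
        return word

    def to_set(self) -> set:
        """Materialize the family (small dimensions only; for tests/oracles)."""
        if self.dimension > 22:
            raise ValueError("refusing to materialize a family of width > 22")
        return set(self._bdd.iter_words(self._root))

    def __repr__(self) -> str:
        return f"SubsetFamilyStore(dimension={self.dimension}, size={len(self)})"


def store_full(dimension: int) -> SubsetFamilyStore:
    """The full family P(S′) of all 2^dimension outer-lattice words."""
    return SubsetFamilyStore.full(dimension)
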