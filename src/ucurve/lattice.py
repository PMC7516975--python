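"""Boolean-lattice primitives for subset search.

The search space of feature selection is the power set P(S) of a ground set S
of features, partially ordered by inclusion.  Subsets are encoded as
fixed-width bit strings whose leftmost digit corresponds to the first feature
in the lexicographic ordering of feature names: over S = {c, b, e, d, a} the
subset {b, e} is the string ``01001``.

This module provides the ground set, the bit-string subset encoding, lattice
intervals, the cost-function contract shared by every search algorithm, and a
memoizing evaluation ledger that counts distinct cost evaluations — the
hardware-independent work measure used throughout the package.
"""

from __future__ import annotations

from collections.abc import Iterable
from typing import Callable


#: Relative tolerance for comparisons of real-valued costs.  Pruning rules use
#: strict inequalities and must not flip on floating-point noise; integer
#: costs are compared exactly.
COST_REL_TOL = 1e-12


def _is_integral(x) -> bool:
    return isinstance(x, int) or (hasattr(x, "is_integer") and float(x).is_integer())


def cost_lt(a, b, rel_tol: float = COST_REL_TOL) -> bool:
    """Strict ``a < b`` for cost values, tolerance-guarded for floats."""
    if isinstance(a, int) and isinstance(b, int):
        return a < b
    return (b - a) > rel_tol * max(1.0, abs(a), abs(b))


def cost_gt(a, b, rel_tol: float = COST_REL_TOL) -> bool:
    """Strict ``a > b`` for cost values, tolerance-guarded for floats."""
    return cost_lt(b, a, rel_tol)


def cost_eq(a, b, rel_tol: float = COST_REL_TOL) -> bool:
    return not cost_lt(a, b, rel_tol) and not cost_lt(b, a, rel_tol)


class GroundSet:
    """An ordered ground set S of feature names.

    Names are unique and held in lexicographic order; bit position ``i`` of a
    :class:`FeatureSet` word refers to the ``i``-th name in this order.
    """

    __slots__ = ("features", "n", "_index")

    def __init__(self, features: Iterable[str]):
        feats = tuple(sorted(str(f) for f in features))
        if len(feats) == 0:
            raise ValueError("ground set must contain at least one feature")
        if len(set(feats)) != len(feats):
            raise ValueError("feature names must be unique")
        self.features = feats
        self.n = len(feats)
        self._index = {name: i for i, name in enumerate(feats)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown feature name: {name!r}") from None

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def subset(self, names: Iterable[str]) -> "FeatureSet":
        return encode_subset(names, self)

    def from_string(self, bits: str) -> "FeatureSet":
        return FeatureSet.from_string(bits, self)

    def all_masks(self) -> range:
        return range(1 << self.n)

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, GroundSet) and self.features == other.features

    def __hash__(self) -> int:
        return hash(self.features)

    def __repr__(self) -> str:
        return f"GroundSet({list(self.features)!r})"


class FeatureSet:
    """A subset of a ground set, stored as an integer bit mask.

    Bit ``i`` of the mask (``mask >> i & 1``) flags presence of the ``i``-th
    lexicographic feature, so the canonical string form reads the mask from
    bit 0 leftwards: ``{b, e}`` over ``{a, b, c, d, e}`` prints as ``01001``.
    """

    __slots__ = ("mask", "ground")

    def __init__(self, mask: int, ground: GroundSet):
        if not 0 <= mask <= ground.full_mask:
            raise ValueError(f"mask {mask:#x} out of range for n={ground.n}")
        self.mask = int(mask)
        self.ground = ground

    @classmethod
    def from_string(cls, bits: str, ground: GroundSet) -> "FeatureSet":
        if len(bits) != ground.n or set(bits) - {"0", "1"}:
            raise ValueError(f"expected a {ground.n}-digit binary string, got {bits!r}")
        mask = 0
        for i, ch in enumerate(bits):
            if ch == "1":
                mask |= 1 << i
        return cls(mask, ground)

    @property
    def bits(self) -> str:
        return "".join("1" if self.mask >> i & 1 else "0" for i in range(self.ground.n))

    def names(self) -> set:
        return {f for i, f in enumerate(self.ground.features) if self.mask >> i & 1}

    def cardinality(self) -> int:
        return self.mask.bit_count()

    def issubset(self, other: "FeatureSet") -> bool:
        self._check_same_ground(other)
        return self.mask & other.mask == self.mask

    def union(self, other: "FeatureSet") -> "FeatureSet":
        self._check_same_ground(other)
        return FeatureSet(self.mask | other.mask, self.ground)

    def intersection(self, other: "FeatureSet") -> "FeatureSet":
        self._check_same_ground(other)
        return FeatureSet(self.mask & other.mask, self.ground)

    def _check_same_ground(self, other: "FeatureSet") -> None:
        if self.ground != other.ground:
            raise ValueError("feature sets are over different ground sets")

    __or__ = union
    __and__ = intersection

    def __le__(self, other: "FeatureSet") -> bool:
        return self.issubset(other)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureSet)
            and self.mask == other.mask
            and self.ground == other.ground
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.ground.features))

    def __repr__(self) -> str:
        return f"FeatureSet({self.bits!r})"


def encode_subset(names: Iterable[str], ground: GroundSet) -> FeatureSet:
    """Encode a set of feature names as a bit-string subset of ``ground``."""
    mask = 0
    for name in names:
        mask |= 1 << ground.index(name)
    return FeatureSet(mask, ground)


def decode_subset(fs: FeatureSet) -> set:
    """Inverse of :func:`encode_subset`."""
    return fs.names()


class Interval:
    """The lattice interval [lower, upper] = {A : lower ⊆ A ⊆ upper}."""

    __slots__ = ("lower", "upper")

    def __init__(self, lower: FeatureSet, upper: FeatureSet):
        if lower.ground != upper.ground:
            raise ValueError("interval endpoints are over different ground sets")
        if not lower.issubset(upper):
            raise ValueError("interval lower bound is not a subset of the upper bound")
        self.lower = lower
        self.upper = upper

    def __contains__(self, A: FeatureSet) -> bool:
        return interval_contains(self, A)

    def __repr__(self) -> str:
        return f"Interval([{self.lower.bits}, {self.upper.bits}])"


def interval_contains(iv: Interval, A: FeatureSet) -> bool:
    """True iff ``iv.lower ⊆ A ⊆ iv.upper`` (bitwise containment test)."""
    if A.ground != iv.lower.ground:
        raise ValueError("subset is over a different ground set than the interval")
    m = A.mask
    return (iv.lower.mask & m == iv.lower.mask) and (m & iv.upper.mask == m)


def mask_in_interval(lower: int, upper: int, mask: int) -> bool:
    """Raw-mask variant of :func:`interval_contains` (internal fast path)."""
    return (lower & mask == lower) and (mask & upper == mask)


class CostFunction:
    """A cost oracle c : P(S) → R≥0.

    Subclasses implement :meth:`evaluate_mask` on raw bit masks; the public
    call interface takes :class:`FeatureSet` objects and checks the ground
    set.  Cost functions must be deterministic and non-negative.
    """

    name: str = "cost"

    def __init__(self, ground: GroundSet):
        self.ground = ground

    def evaluate_mask(self, mask: int):
        raise NotImplementedError

    def __call__(self, A: FeatureSet):
        if A.ground != self.ground:
            raise ValueError(
                f"subset {A.bits} is over a different ground set than cost {self.name!r}"
            )
        return self.evaluate_mask(A.mask)


class FunctionCost(CostFunction):
    """Adapter wrapping a plain ``mask -> cost`` callable."""

    def __init__(self, ground: GroundSet, fn: Callable[[int], float], name: str = "fn"):
        super().__init__(ground)
        self._fn = fn
        self.name = name

    def evaluate_mask(self, mask: int):
        return self._fn(mask)


class EvaluationLedger:
    """Memo of evaluated subsets and count of distinct cost-function calls.

    ``computed`` maps raw masks to costs (the record M of evaluated
    elements); ``distinct_calls`` equals the number of keys — a memo hit
    never increments it.  This is the hardware-independent work measure
    reported by every search algorithm.
    """

    __slots__ = ("computed",)

    def __init__(self):
        self.computed: dict = {}

    @property
    def distinct_calls(self) -> int:
        return len(self.computed)

    def evaluate_mask(self, c: CostFunction, mask: int):
        memo = self.computed
        try:
            return memo[mask]
        except KeyError:
            pass
        try:
            value = c.evaluate_mask(mask)
        except Exception as exc:
            raise RuntimeError(
                f"cost evaluation failed on subset mask {mask:b}"
            ) from exc
        memo[mask] = value
        return value

    def best(self):
        """(mask, cost) of the best-so-far evaluated subset, or None."""
        if not self.computed:
            return None
        mask = min(self.computed, key=lambda m: (self.computed[m], m))
        return mask, self.computed[mask]

    def minima_masks(self) -> list:
        if not self.computed:
            return []
        best = min(self.computed.values())
        return sorted(m for m, v in self.computed.items() if v == best)

    def merge(self, other: "EvaluationLedger") -> None:
        self.computed.update(other.computed)


def evaluate_memoized(c: CostFunction, ledger: EvaluationLedger, A: FeatureSet):
    """Evaluate c(A) through the ledger: memoized, distinct-call counted."""
    if A.ground != c.ground:
        raise ValueError("subset is over a different ground set than the cost function")
    return ledger.evaluate_mask(c, A.mask)


#: Largest n for which the exhaustive U-decomposability check will run.
U_DECOMPOSABLE_MAX_N = 14


def is_u_decomposable(c: CostFunction, ground: GroundSet | None = None,
                      max_n: int = U_DECOMPOSABLE_MAX_N) -> bool:
    """Exhaustively check decomposability in U-shaped curves (small n only).

    A cost is decomposable in U-shaped curves when every chain triple
    X1 ⊆ X2 ⊆ X3 satisfies c(X2) ≤ max{c(X1), c(X3)}.  Checking triples of
    consecutive cardinality suffices: any violation on a wider chain implies
    a consecutive one (along a chain, a strict interior maximum implies a
    strict local maximum).
    """
    ground = ground or c.ground
    n = ground.n
    if n > max_n:
        raise ValueError(
            f"exhaustive U-decomposability check limited to n <= {max_n}, got n={n}"
        )
    # A triple (X1, X2, X3) violates iff c(X2) > c(X1) and c(X2) > c(X3); the
    # lower and upper neighbours are chosen independently, so a violation at
    # X2 exists iff some lower neighbour and some upper neighbour are both
    # strictly cheaper than X2.
    costs = [c.evaluate_mask(m) for m in range(1 << n)]
    full = ground.full_mask
    for m in range(1 << n):
        if m == 0 or m == full:
            continue  # no complete consecutive triple through top or bottom
        cm = costs[m]
        cheaper_below = False
        inside = m
        while inside:
            b = inside & -inside
            if cost_gt(cm, costs[m ^ b]):
                cheaper_below = True
                break
            inside ^= b
        if not cheaper_below:
            continue
        outside = full ^ m
        while outside:
            b = outside & -outside
            if cost_gt(cm, costs[m | b]):
                return False
            outside ^= b
    return True
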