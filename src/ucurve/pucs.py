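"""Parallel U-curve search (PUCS) over a partitioned Boolean lattice.

The ground set S is split into a fixed set S′ (|S′| = ⌈p·|S|⌉) and its
complement, the free set.  Every element X of the outer Boolean lattice
P(S′) anchors an inner Boolean lattice {X ∪ Y : Y ⊆ S′¯}; the 2^|S′| inner
lattices are pairwise disjoint and cover P(S).  A walk over the outer
lattice compares, for adjacent outer elements, the costs of their inner
floors c(X) and ceilings c(X ∪ S′¯); on a cost decomposable in U-shaped
curves a strict inequality lets a whole interval of P(S) be discarded
without risking the global minimum:

* c(X) < c(Y) with X ⊂ Y removes [Y, S]   (every Z ⊇ Y costs more than X);
* c(X ∪ S′¯) > c(Y ∪ S′¯) with X ⊂ Y removes [∅, X ∪ S′¯].

Inner lattices that survive the walk are solved independently — recursively
by the same partition scheme up to depth ``l``, and by a pluggable base
algorithm at the deepest level — which is the natural parallel region: a
coordinator runs the walk, workers solve inner lattices with private
evaluation ledgers that are merged at the end.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Sequence

import numpy as np

from .algorithms import SearchResult, get_base_algorithm
from .costs import ProjectedCost
from .lattice import (
    CostFunction,
    EvaluationLedger,
    FeatureSet,
    GroundSet,
    cost_gt,
    cost_lt,
    mask_in_interval,
)
from .store import SubsetFamilyStore


# ---------------------------------------------------------------------------
# Partition of P(S) into outer/inner Boolean lattices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Fixed set S′, free set S′¯ and the outer/inner coordinate maps."""

    ground: GroundSet
    fixed_idx: tuple

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.fixed_idx)))
        if any(i < 0 or i >= self.ground.n for i in idx):
            raise ValueError("fixed-point index out of range")
        object.__setattr__(self, "fixed_idx", idx)

    @property
    def free_idx(self) -> tuple:
        fixed = set(self.fixed_idx)
        return tuple(i for i in range(self.ground.n) if i not in fixed)

    @property
    def dim(self) -> int:
        """Width of the outer lattice words, |S′|."""
        return len(self.fixed_idx)

    @property
    def fixed(self) -> FeatureSet:
        mask = 0
        for i in self.fixed_idx:
            mask |= 1 << i
        return FeatureSet(mask, self.ground)

    @property
    def free(self) -> FeatureSet:
        return FeatureSet(self.ground.full_mask ^ self.fixed.mask, self.ground)

    @property
    def n_inner_lattices(self) -> int:
        """One inner Boolean lattice per outer element: 2^|S′|."""
        return 1 << self.dim

    def embed_outer(self, word: int) -> int:
        """Map an outer-lattice word onto its full-space anchor mask."""
        mask = 0
        for j, i in enumerate(self.fixed_idx):
            if word >> j & 1:
                mask |= 1 << i
        return mask

    def restrict_outer(self, mask: int) -> int:
        """Project a full-space mask onto outer-lattice coordinates."""
        word = 0
        for j, i in enumerate(self.fixed_idx):
            if mask >> i & 1:
                word |= 1 << j
        return word

    def inner_members(self, word: int):
        """All full-space masks of the inner lattice anchored at ``word``."""
        anchor = self.embed_outer(word)
        free = self.free_idx
        for sub in range(1 << len(free)):
            m = anchor
            for j, i in enumerate(free):
                if sub >> j & 1:
                    m |= 1 << i
            yield m


def make_partition(ground: GroundSet, p: float,
                   rng: np.random.Generator | None = None,
                   fixed: Sequence[str] | None = None) -> Partition:
    """Choose the fixed set S′: |S′| = ⌈p·n⌉ features.

    Membership is drawn uniformly at random with the seeded generator unless
    an explicit list of feature names is supplied.
    """
    if fixed is not None:
        idx = tuple(ground.index(name) for name in fixed)
        return Partition(ground, idx)
    if not 0 < p <= 1:
        raise ValueError(f"fixed-set proportion p must be in (0, 1], got {p}")
    k = ceil(p * ground.n)
    rng = rng if rng is not None else np.random.default_rng()
    idx = tuple(int(i) for i in rng.choice(ground.n, size=k, replace=False))
    return Partition(ground, idx)


# ---------------------------------------------------------------------------
# Parameters and walk state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PUCSParams:
    """Tunables of the partitioned search.

    ``p`` — fraction of features fixed (outer-lattice size 2^⌈p·n⌉);
    ``l`` — maximum recursion depth before the base algorithm runs;
    ``base`` — leaf solver ("ubb", "es", "sfs", "sffs");
    ``seed`` — drives partition choice and all random walk decisions;
    ``workers`` — inner lattices solved concurrently (1 = sequential);
    ``fixed`` — optional explicit fixed-point names, overriding the random
    draw at the top level.
    """

    p: float = 0.5
    l: int = 1
    base: str = "ubb"
    seed: int = 0
    workers: int = 1
    fixed: tuple | None = None

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.l < 1:
            raise ValueError(f"recursion depth l must be >= 1, got {self.l}")
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        get_base_algorithm(self.base)  # fail fast on unknown identifiers


def default_params(n: int, **overrides) -> PUCSParams:
    """Instance-size defaults: small instances (n ≤ 25) use an optimal leaf
    (UBB, p = 0.5); larger ones a greedy leaf (SFS, p = 10/n)."""
    if n <= 25:
        base = dict(p=0.5, l=1, base="ubb")
    else:
        base = dict(p=10.0 / n, l=1, base="sfs")
    base.update(overrides)
    return PUCSParams(**base)


class AdjacencyCase(enum.Enum):
    """Outcome of the five-branch adjacency test, in evaluation order."""

    PRUNE_LOWER_MOVE = "prune_lower_move"    # X ⊂ Y, ceiling(X) > ceiling(Y)
    PRUNE_UPPER_STAY = "prune_upper_stay"    # X ⊂ Y, floor(X) < floor(Y)
    PRUNE_UPPER_MOVE = "prune_upper_move"    # Y ⊂ X, floor(Y) < floor(X)
    PRUNE_LOWER_STAY = "prune_lower_stay"    # Y ⊂ X, ceiling(Y) > ceiling(X)
    MOVE = "move"                            # no strict inequality fires


@dataclass(frozen=True)
class PruneEvent:
    """One fired pruning rule, recorded as the removed full-space interval
    and its outer-lattice projection."""

    rule: str                 # "corollary" (lower interval) or "proposition"
    case: AdjacencyCase
    outer_lower: int
    outer_upper: int
    lower_mask: int           # full-space interval actually discarded
    upper_mask: int

    def covers_mask(self, mask: int) -> bool:
        return mask_in_interval(self.lower_mask, self.upper_mask, mask)


@dataclass
class WalkState:
    """Mutable state of one outer walk: the unexplored store U, the live
    explored set E, and the pruning/exploration record."""

    store: SubsetFamilyStore
    explored: set = field(default_factory=set)
    events: list = field(default_factory=list)
    visit_order: list = field(default_factory=list)


@dataclass(frozen=True)
class WalkResult:
    survivors: tuple
    events: tuple
    visit_order: tuple


def probe_costs(word: int, part: Partition, cost: CostFunction,
                ledger: EvaluationLedger):
    """Floor and ceiling costs of the inner lattice anchored at ``word``:
    c(X) with free bits 0 and c(X ∪ S′¯) with free bits 1, memoized."""
    anchor = part.embed_outer(word)
    floor = ledger.evaluate_mask(cost, anchor)
    ceiling = ledger.evaluate_mask(cost, anchor | part.free.mask)
    return floor, ceiling


def adjacency_case(x_word: int, y_word: int, x_probes, y_probes) -> AdjacencyCase:
    """Classify an adjacent outer pair by the five-branch test.

    Branches are evaluated strictly in order: ceiling comparison before the
    floor comparison in the upward direction, floor before ceiling downward,
    else a plain move.
    """
    if (x_word ^ y_word).bit_count() != 1:
        raise ValueError(
            f"outer elements {x_word:b} and {y_word:b} are not adjacent"
        )
    floor_x, ceil_x = x_probes
    floor_y, ceil_y = y_probes
    x_below = x_word & y_word == x_word
    if x_below:
        if cost_gt(ceil_x, ceil_y):
            return AdjacencyCase.PRUNE_LOWER_MOVE
        if cost_lt(floor_x, floor_y):
            return AdjacencyCase.PRUNE_UPPER_STAY
    else:
        if cost_lt(floor_y, floor_x):
            return AdjacencyCase.PRUNE_UPPER_MOVE
        if cost_gt(ceil_y, ceil_x):
            return AdjacencyCase.PRUNE_LOWER_STAY
    return AdjacencyCase.MOVE


def _record_prune(state: WalkState, part: Partition, case: AdjacencyCase,
                  outer_lower: int, outer_upper: int) -> None:
    """Remove an outer interval from U and E and log the corresponding
    full-space interval.

    Removing outer elements in [A, B] discards the union of their inner
    lattices, i.e. the full-space interval [embed(A), embed(B) ∪ S′¯]; this
    is exactly the region the fired rule licenses.
    """
    state.store.remove_interval(outer_lower, outer_upper)
    doomed = [w for w in state.explored
              if mask_in_interval(outer_lower, outer_upper, w)]
    for w in doomed:
        state.explored.discard(w)
    rule = ("corollary" if case in (AdjacencyCase.PRUNE_LOWER_MOVE,
                                    AdjacencyCase.PRUNE_LOWER_STAY)
            else "proposition")
    state.events.append(PruneEvent(
        rule=rule,
        case=case,
        outer_lower=outer_lower,
        outer_upper=outer_upper,
        lower_mask=part.embed_outer(outer_lower),
        upper_mask=part.embed_outer(outer_upper) | part.free.mask,
    ))


def outer_walk(part: Partition, cost: CostFunction, ledger: EvaluationLedger,
               rng: np.random.Generator,
               state: WalkState | None = None) -> WalkResult:
    """Walk the outer Boolean lattice, pruning as Proposition/Corollary
    conditions fire, until the unexplored store U is exhausted.

    Walk starts and adjacency exploration use seeded random choices; the
    adjacency list of the current element is re-derived whenever the walk
    moves.  Returns the surviving explored elements, the pruning log and the
    visit order.
    """
    dim = part.dim
    state = state if state is not None else WalkState(SubsetFamilyStore.full(dim))
    store, E = state.store, state.explored
    full_outer = (1 << dim) - 1

    while not store.is_empty():
        x = store.pop(rng)
        E.add(x)
        state.visit_order.append(x)
        while True:
            moved = False
            order = rng.permutation(dim) if dim else []
            for i in order:
                y = x ^ (1 << int(i))
                if not store.contains(y):
                    continue
                px = probe_costs(x, part, cost, ledger)
                py = probe_costs(y, part, cost, ledger)
                case = adjacency_case(x, y, px, py)
                if case is AdjacencyCase.PRUNE_LOWER_MOVE:
                    _record_prune(state, part, case, 0, x)
                elif case is AdjacencyCase.PRUNE_UPPER_STAY:
                    _record_prune(state, part, case, y, full_outer)
                    continue
                elif case is AdjacencyCase.PRUNE_UPPER_MOVE:
                    _record_prune(state, part, case, x, full_outer)
                elif case is AdjacencyCase.PRUNE_LOWER_STAY:
                    _record_prune(state, part, case, 0, y)
                    continue
                # move cases (i, iii, v): Y becomes the current element and
                # is inserted into E after any interval removal
                store.discard(y)
                x = y
                E.add(x)
                state.visit_order.append(x)
                moved = True
                break
            if not moved:
                break
    return WalkResult(
        survivors=tuple(sorted(E)),
        events=tuple(state.events),
        visit_order=tuple(state.visit_order),
    )


# ---------------------------------------------------------------------------
# Inner-lattice solving and the full search
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, level: int, word: int) -> int:
    ss = np.random.SeedSequence((int(seed), int(level), int(word)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def solve_inner(word: int, part: Partition, cost: CostFunction,
                ledger: EvaluationLedger, params: PUCSParams,
                level: int = 1) -> list:
    """Find the minima of the inner lattice anchored at ``word``.

    Below the maximum recursion depth, the same partitioned search runs on
    the projected instance ⟨S′¯, c_X⟩; at the deepest level the base
    algorithm is dispatched.  Returns (full-space mask, cost) pairs for the
    inner minima.
    """
    anchor = part.embed_outer(word)
    free_idx = part.free_idx
    if not free_idx:
        return [(anchor, ledger.evaluate_mask(cost, anchor))]
    proj = ProjectedCost(cost, anchor, free_idx, ledger=ledger)
    sub_seed = _derive_seed(params.seed, level, word)
    if level < params.l and len(free_idx) > 1:
        sub_params = replace(params, seed=sub_seed, workers=1, fixed=None)
        res = pucs_search(proj.ground, proj, sub_params, _level=level + 1)
        return [(proj.full_mask_of(fs.mask), res.best_cost) for fs in res.minima]
    algo = get_base_algorithm(params.base)
    sub_ledger = EvaluationLedger()
    result: SearchResult = algo(proj.ground, proj, sub_ledger)
    return [(proj.full_mask_of(fs.mask), result.best_cost) for fs in result.minima]


def _inner_task(word: int, part: Partition, cost: CostFunction,
                params: PUCSParams, level: int):
    """Worker entry point: solve one inner lattice with a private ledger."""
    ledger = EvaluationLedger()
    minima = solve_inner(word, part, cost, ledger, params, level)
    return minima, ledger.computed


@dataclass(frozen=True)
class PUCSResult:
    """Search outcome: all evaluated elements attaining the minimum
    evaluated cost, plus the merged ledger and the pruning record."""

    minima: tuple
    best_cost: float
    ledger: EvaluationLedger
    events: tuple
    partition: Partition
    params: PUCSParams
    survivors: tuple = ()

    @property
    def n_calls(self) -> int:
        return self.ledger.distinct_calls

    @property
    def best_subset(self) -> FeatureSet:
        return self.minima[0]


def pucs_search(ground: GroundSet, cost: CostFunction, params: PUCSParams,
                *, _level: int = 1) -> PUCSResult:
    """Run the full partitioned U-curve search on ⟨S, c⟩.

    Reproducible for a fixed seed; the minima set and the merged-ledger
    distinct-call count are invariant to the worker count because every
    inner lattice is solved deterministically under a seed derived from the
    run seed and its anchor.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(params.seed), _level)))
    ledger = EvaluationLedger()
    part = make_partition(ground, params.p, rng,
                          fixed=params.fixed if _level == 1 else None)
    walk = outer_walk(part, cost, ledger, rng)

    survivors = walk.survivors
    if params.workers > 1 and len(survivors) > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=params.workers)(
            delayed(_inner_task)(w, part, cost, params, _level) for w in survivors
        )
        for _minima, computed in outcomes:
            ledger.computed.update(computed)
    else:
        for w in survivors:
            solve_inner(w, part, cost, ledger, params, _level)

    best_cost = min(ledger.computed.values())
    minima = tuple(FeatureSet(m, ground)
                   for m in sorted(ledger.computed)
                   if ledger.computed[m] == best_cost)
    return PUCSResult(
        minima=minima,
        best_cost=best_cost,
        ledger=ledger,
        events=walk.events,
        partition=part,
        params=params,
        survivors=survivors,
    )
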