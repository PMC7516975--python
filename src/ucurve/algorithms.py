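"""Base search algorithms over the Boolean lattice.

These solvers run standalone or as the leaf solver dispatched on inner
Boolean lattices by the partitioned search:

* ``exhaustive_search`` (ES) — evaluates every subset; the optimal oracle.
* ``ubb_search`` — U-curve branch and bound: a depth-first enumeration of a
  spanning tree of P(S) that cuts whole subtrees when the cost strictly
  increases along an edge; optimal whenever the cost is decomposable in
  U-shaped curves.
* ``sfs_search`` — sequential forward selection (greedy additions).
* ``sffs_search`` — sequential forward floating selection (greedy additions
  with conditional backward removals, stopping delta cardinalities past the
  incumbent best).

All solvers share the memoized evaluation ledger, report distinct
cost-function calls, and are deterministic under the stated tie-breaks
(lowest feature index wins).
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import (
    CostFunction,
    EvaluationLedger,
    FeatureSet,
    GroundSet,
    cost_lt,
)

#: Default guard on exhaustive-style enumeration, matching the boundary
#: between instances that optimal algorithms can still solve and those that
#: cannot (about 25 features).
ENUMERATION_GUARD = 25


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one search: the minima it found, their cost, the ledger."""

    minima: tuple
    best_cost: float
    ledger: EvaluationLedger

    @property
    def n_calls(self) -> int:
        return self.ledger.distinct_calls

    @property
    def best_subset(self) -> FeatureSet:
        return self.minima[0]


def _finish(ground: GroundSet, ledger: EvaluationLedger, local: dict) -> SearchResult:
    best = min(local.values())
    minima = tuple(
        FeatureSet(m, ground) for m in sorted(local) if local[m] == best
    )
    return SearchResult(minima=minima, best_cost=best, ledger=ledger)


def _guard(n: int, guard: int, force: bool, algo: str) -> None:
    if n > guard and not force:
        raise ValueError(
            f"{algo} enumerates up to 2^n subsets and refuses n={n} > {guard}; "
            "pass force=True to override"
        )


def exhaustive_search(ground: GroundSet, cost: CostFunction,
                      ledger: EvaluationLedger | None = None, *,
                      guard: int = ENUMERATION_GUARD,
                      force: bool = False) -> SearchResult:
    """Evaluate all 2^n subsets; distinct calls equal exactly 2^n on a fresh
    ledger."""
    n = ground.n
    _guard(n, guard, force, "exhaustive search")
    ledger = ledger if ledger is not None else EvaluationLedger()
    local = {}
    ev = ledger.evaluate_mask
    for m in range(1 << n):
        local[m] = ev(cost, m)
    return _finish(ground, ledger, local)


def ubb_search(ground: GroundSet, cost: CostFunction,
               ledger: EvaluationLedger | None = None, *,
               guard: int = ENUMERATION_GUARD,
               force: bool = False) -> SearchResult:
    """U-curve branch and bound.

    P(S) is enumerated as a spanning tree: the children of X append only
    features of index greater than X's highest set index, so every subset is
    generated exactly once.  When the edge X → X∪{s} strictly increases the
    cost, every superset of X∪{s} on that subtree lies in [X∪{s}, S] and is
    at least as costly on a U-decomposable instance, so the subtree is cut.
    """
    n = ground.n
    _guard(n, guard, force, "U-curve branch and bound")
    ledger = ledger if ledger is not None else EvaluationLedger()
    local = {}
    ev = ledger.evaluate_mask

    def visit(mask: int, cmask, top: int) -> None:
        for s in range(top + 1, n):
            child = mask | (1 << s)
            cchild = ev(cost, child)
            local[child] = cchild
            if not cost_lt(cmask, cchild):
                visit(child, cchild, s)

    c0 = ev(cost, 0)
    local[0] = c0
    visit(0, c0, -1)
    return _finish(ground, ledger, local)


def sfs_search(ground: GroundSet, cost: CostFunction,
               ledger: EvaluationLedger | None = None) -> SearchResult:
    """Sequential forward selection.

    Starting at ∅, repeatedly add the single feature whose addition yields
    the lowest cost (ties: lowest feature index); stop as soon as no
    addition strictly improves the best cost seen.
    """
    n = ground.n
    ledger = ledger if ledger is not None else EvaluationLedger()
    local = {}
    ev = ledger.evaluate_mask
    current = 0
    best = local[0] = ev(cost, 0)
    while current.bit_count() < n:
        cand_mask, cand_cost = None, None
        for s in range(n):
            if current >> s & 1:
                continue
            m = current | (1 << s)
            v = ev(cost, m)
            local[m] = v
            if cand_cost is None or cost_lt(v, cand_cost):
                cand_mask, cand_cost = m, v
        if not cost_lt(cand_cost, best):
            break
        current, best = cand_mask, cand_cost
    return _finish(ground, ledger, local)


def sffs_search(ground: GroundSet, cost: CostFunction,
                ledger: EvaluationLedger | None = None, *,
                delta: int = 3) -> SearchResult:
    """Sequential forward floating selection with look-beyond ``delta``.

    Forward steps add the best single feature; after each forward step,
    backward steps remove a feature while the removal strictly improves the
    best cost recorded at the smaller cardinality.  The search halts once
    the current cardinality exceeds the incumbent best's cardinality by
    more than ``delta`` (or the full set is reached).
    """
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    n = ground.n
    ledger = ledger if ledger is not None else EvaluationLedger()
    local = {}
    ev = ledger.evaluate_mask

    current = 0
    ccur = local[0] = ev(cost, 0)
    best_at_card = {0: ccur}
    best_cost, best_card = ccur, 0

    def note(mask: int, value) -> None:
        nonlocal best_cost, best_card
        k = mask.bit_count()
        if k not in best_at_card or cost_lt(value, best_at_card[k]):
            best_at_card[k] = value
        if cost_lt(value, best_cost):
            best_cost, best_card = value, k

    while True:
        k = current.bit_count()
        if k >= n or k > best_card + delta:
            break
        # forward: best single addition
        add_mask, add_cost = None, None
        for s in range(n):
            if current >> s & 1:
                continue
            m = current | (1 << s)
            v = ev(cost, m)
            local[m] = v
            if add_cost is None or cost_lt(v, add_cost):
                add_mask, add_cost = m, v
        current, ccur = add_mask, add_cost
        note(current, ccur)
        # conditional backward: strict improvement at the smaller cardinality
        while current.bit_count() > 1:
            k = current.bit_count()
            rem_mask, rem_cost = None, None
            for s in range(n):
                if not (current >> s & 1):
                    continue
                m = current ^ (1 << s)
                v = ev(cost, m)
                local[m] = v
                if rem_cost is None or cost_lt(v, rem_cost):
                    rem_mask, rem_cost = m, v
            if cost_lt(rem_cost, best_at_card.get(k - 1, float("inf"))):
                current, ccur = rem_mask, rem_cost
                note(current, ccur)
            else:
                break
    return _finish(ground, ledger, local)


BASE_ALGORITHMS = {
    "es": exhaustive_search,
    "ubb": ubb_search,
    "sfs": sfs_search,
    "sffs": sffs_search,
}


def get_base_algorithm(name: str):
    try:
        return BASE_ALGORITHMS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown base algorithm {name!r}; choose from {sorted(BASE_ALGORITHMS)}"
        ) from None
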