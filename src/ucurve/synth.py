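"""Synthetic instance generators and the oscillation statistic.

Hard benchmark instances come from the subset-sum reduction: drawing n
random integer weights and a random target yields a cost |t − Σ w| that is
provably decomposable in U-shaped curves yet NP-hard to minimize.  Noisy
classification tables emulate the training data of window-based image
operators: binary feature vectors with a label computed by a planted Boolean
function of a few features and then corrupted by salt-and-pepper-style label
flips.  The oscillation count measures how far a real cost function departs
from the U-curve assumption.
"""

from __future__ import annotations

import numpy as np

from .costs import SampleTable, SubsetSumInstance
from .lattice import CostFunction, FeatureSet, GroundSet, cost_gt


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def gen_subset_sum_instance(n: int, rng=None) -> SubsetSumInstance:
    """Random subset-sum instance with ``n`` features.

    Draws n + 1 random integers: the weights uniformly on {0, …, 10·n} and
    the target uniformly on {0, …, Σ weights}, so the optimum is neither ∅
    nor S systematically and the instance stays hard in the subset-sum
    sense.  Bit-reproducible for a seeded generator.
    """
    if n < 1:
        raise ValueError(f"instance size must be >= 1, got {n}")
    rng = _as_rng(rng)
    weights = rng.integers(0, 10 * n + 1, size=n)
    target = int(rng.integers(0, int(weights.sum()) + 1))
    width = max(2, len(str(n - 1)))
    names = {f"w{i:0{width}d}": int(w) for i, w in enumerate(weights)}
    return SubsetSumInstance(weights=names, target=target)


def gen_mce_dataset(n: int, k: int, noise_rate: float, t: int, rng=None,
                    rule: str = "parity") -> SampleTable:
    """Noisy discrete classification table with a planted feature subset.

    Binary feature vectors are uniform at random; the label is a fixed
    Boolean function (parity or majority) of ``k`` planted features and is
    then flipped with probability ``noise_rate`` — the label-flip analogue
    of covering a binary image with uniformly distributed salt-and-pepper
    noise.  The planted subset is recorded on the returned table as ground
    truth.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if not 0 <= noise_rate < 0.5:
        raise ValueError(f"noise rate must be in [0, 0.5), got {noise_rate}")
    if t < 1:
        raise ValueError(f"sample count must be >= 1, got {t}")
    if rule not in ("parity", "majority"):
        raise ValueError(f"label rule must be 'parity' or 'majority', got {rule!r}")
    rng = _as_rng(rng)
    X = rng.integers(0, 2, size=(t, n))
    planted_idx = np.sort(rng.choice(n, size=k, replace=False))
    planted_cols = X[:, planted_idx]
    if rule == "parity":
        y = planted_cols.sum(axis=1) % 2
    else:
        y = (planted_cols.sum(axis=1) * 2 > k).astype(np.int64)
    flips = rng.random(t) < noise_rate
    y = np.where(flips, 1 - y, y)
    width = max(2, len(str(n - 1)))
    names = [f"f{i:0{width}d}" for i in range(n)]
    table = SampleTable(names, X, y, labels=(0, 1))
    ground = table.ground
    planted_mask = 0
    for i in planted_idx:
        planted_mask |= 1 << ground.index(names[int(i)])
    table.planted = FeatureSet(planted_mask, ground)
    return table


#: Largest n for which the exhaustive oscillation scan will run.
OSCILLATION_GUARD = 16


def count_oscillations(ground: GroundSet, c: CostFunction,
                       guard: int = OSCILLATION_GUARD) -> int:
    """Count U-curve violations on consecutive-cardinality chain triples.

    An oscillation is an ordered triple X1 ⊂ X2 ⊂ X3 with |X2| = |X1| + 1,
    |X3| = |X2| + 1 and c(X2) > max{c(X1), c(X3)}.  Each qualifying (X1, X2,
    X3) triple counts once; the per-element oscillation ratio of an instance
    is this count divided by 2^n.
    """
    n = ground.n
    if n > guard:
        raise ValueError(
            f"exhaustive oscillation scan limited to n <= {guard}, got n={n}"
        )
    costs = [c.evaluate_mask(m) for m in range(1 << n)]
    full = ground.full_mask
    total = 0
    for m in range(1 << n):
        if m == 0 or m == full:
            continue
        cm = costs[m]
        below = 0
        inside = m
        while inside:
            b = inside & -inside
            if cost_gt(cm, costs[m ^ b]):
                below += 1
            inside ^= b
        if not below:
            continue
        above = 0
        outside = full ^ m
        while outside:
            b = outside & -outside
            if cost_gt(cm, costs[m | b]):
                above += 1
            outside ^= b
        total += below * above
    return total


def oscillation_ratio(ground: GroundSet, c: CostFunction,
                      guard: int = OSCILLATION_GUARD) -> float:
    """Oscillations per search-space element: count / 2^n."""
    return count_oscillations(ground, c, guard) / (1 << ground.n)
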