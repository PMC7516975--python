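# Methods

## The U-curve problem and the pruning rules

The search space is the Boolean lattice `(P(S), ⊆)` of all subsets of a
feature set `S`, |S| = n. A cost function `c : P(S) → R≥0` is *decomposable
in U-shaped curves* when every chain triple `X₁ ⊆ X₂ ⊆ X₃` satisfies
`c(X₂) ≤ max{c(X₁), c(X₃)}`: along any chain the cost dips and then rises,
the signature of estimation criteria under limited samples (too few features
underfit, too many overfit). Minimizing such a cost is NP-hard — the
subset-sum embedding below is an exact reduction — so all optimal algorithms
here are worst-case exponential; pruning controls the constant.

Two facts license pruning. For `X ⊂ Y`:

* if `c(X) < c(Y)`, every `Z ∈ [Y, S]` has `c(Z) > c(X)` (otherwise the
  chain X ⊂ Y ⊂ Z would have a strict interior maximum at Y), so `[Y, S]`
  cannot contain a global minimum not already dominated by `X`;
* dually, if `c(X ∪ S′̄) > c(Y ∪ S′̄)` then every `Z ∈ [∅, X ∪ S′̄]`
  satisfies `c(Z) > c(Y ∪ S′̄)` and the lower interval can be discarded.

Both tests use *strict* inequalities. Integer-valued costs are compared
exactly; real-valued costs through a relative tolerance of 1e-12
(`cost_lt`), so that floating noise can never flip a pruning decision into
unsoundness. Ties never prune.

## The partitioned search

A fixed set `S′` of `⌈p·n⌉` features is chosen uniformly at random with the
run's seed (no selection criterion is known to dominate; an explicit
override is exposed for reproducible studies). Each outer-lattice element
`X ∈ P(S′)` anchors the inner lattice `{X ∪ Y : Y ⊆ S′̄}`; the `2^|S′|`
inner lattices are pairwise disjoint and cover `P(S)`.

The walk pops a random unexplored outer element and examines its outer
neighbours in seeded-random order, re-deriving the adjacency list whenever
the walk advances. The five-branch adjacency test runs in a fixed order
(upward: ceiling rule before floor rule; downward: floor before ceiling;
otherwise move without pruning); every branch either removes the neighbour
from the unexplored store or advances onto it, so the walk terminates after
at most `2^|S′|` removals. When a fired rule removes the current element
itself (the two "move" pruning branches), the walk advances first and
re-inserts the new position into the explored set after the interval
removal, so the position always survives. Interval removals are projected
onto the outer lattice: discarding `[∅, X ∪ S′̄]` removes outer elements in
`[∅, X]`, discarding `[Y, S]` removes `[Y, S′]` — sound because an outer
element's whole inner lattice lies inside the corresponding full-space
interval. Every removal is logged as a pruning event carrying both the
outer and the full-space interval, which is what the soundness checks
audit.

Surviving inner lattices are solved through the wrapper cost
`c_X(Y) = c(X ∪ Y)` on the free coordinates: recursively by the same scheme
while the level is below `l` (the fixed-set rule `⌈p·k⌉` re-applied to the
current free count; recursion also bottoms out when one free feature is
left), and by the base algorithm at the deepest level. The result is the
set of evaluated elements attaining the minimum evaluated cost; with an
optimal base and a U-decomposable cost this is exactly the set of global
minima.

**Parallel contract.** A coordinator runs the walk; surviving inner
lattices are dispatched to joblib workers, each with a private evaluation
ledger, merged by mask union at the end. Each inner lattice's solve is
deterministic given a seed derived from (run seed, level, anchor), so the
minima set and the merged distinct-call count are invariant to the worker
count. Sharing the memo across workers would need synchronization for no
change in the result, so it is deliberately avoided; concurrent multi-walk
parallelism is out of scope.

**Work accounting.** "Cost-function calls" always means distinct
evaluations in the (merged) ledger: a memo hit is free. Exhaustive search
on a fresh ledger therefore reports exactly `2^n`.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `p` ∈ (0,1] | fixed-set fraction; outer width `⌈p·n⌉` | 0.5 (n ≤ 25), else 10/n | moderate granularity: enough parts to prune/parallelize, not so many that probes dominate |
| `l` ≥ 1 | max recursion depth before the base runs | 1 | deeper recursion buys little once inner lattices are small |
| `base` | leaf solver | `ubb` (n ≤ 25), else `sfs` | optimal leaf where enumeration is feasible; greedy leaf beyond |
| `seed` | drives partition choice, walk order, pops | — | all randomness is owned by the run, never global |
| `workers` | parallel inner solves | 1 | result invariant by construction |
| SFFS `delta` | stop `delta` cardinalities past the incumbent | 3 | the customary floating-search look-beyond |

Enumeration-based solvers (ES, UBB, the U-decomposability and oscillation
scans) refuse n above a guard (25 for search, 14/16 for the scans) unless
forced, reflecting the boundary between instances optimal algorithms can
still finish and those they cannot.

## Base algorithms

*UBB* enumerates `P(S)` as a spanning tree (children append only features
above the parent's highest index, so each subset appears once) and cuts the
subtree below a child whenever the edge strictly increases the cost; on a
U-decomposable cost the cut subtree lies in `[child, S]` and is dominated,
so UBB is optimal there. *SFS* greedily adds the best single feature and
stops when no addition strictly improves the incumbent; ties break to the
lowest feature index, making it deterministic. *SFFS* adds floating
backward steps accepted only on strict improvement over the best recorded
cost at the smaller cardinality, halting once the cardinality exceeds the
incumbent best's by more than `delta`.

## Cost functions

**Subset-sum**: `c(X) = |t − Σ_{x∈X} w_x|`. Below the target, growing `X`
can only shrink the deficit; above it, shrinking `X` can only shrink the
excess — so every chain is U-shaped, and `c(X) = 0` iff `X` certifies the
subset-sum instance. This is both the hardness reduction and the synthetic
instance generator: weights are drawn uniformly on `{0, …, 10n}` and the
target uniformly on `{0, …, Σw}` (the distribution of the "n+1 random
integers" is otherwise unspecified; this choice keeps the optimum away from
`∅` and `S` and the instances hard in the subset-sum sense, and is fixed
once — published call counts for other generators are order-of-magnitude
references only).

**Penalized MCE**: for a discrete sample table with `t` samples and label
alphabet `L`,

```
c(X) = N/t + Σ_{x : count(x) ≥ 2} Ĥ(Y | X = x) · count(x)/t
```

where `N` is the number of samples whose X-projection is observed exactly
once and `Ĥ` is the plug-in conditional entropy with logarithm base `|L|`.
The base-`|L|` choice makes the uniform distribution's entropy exactly 1,
so a singleton realization — charged as uniform — contributes exactly
`1/t`, keeping the penalty and the entropy sum on one scale for any number
of classes (with base 2 and `|L| > 2` the printed `N/t` penalty would
understate the uniform-distribution charge). "Observed exactly once" is
read strictly: counts ≥ 2 enter the entropy sum; integer counts make ties
impossible. Features must be discrete; continuous inputs are discretized
upstream.

## Synthetic classification tables

`gen_mce_dataset` emulates window-operator training data: uniform binary
feature vectors, a label computed by a planted Boolean function (parity by
default — the canonical fully multivariate signal; majority optional) of
`k` planted features, then flipped with probability `noise_rate` (default
0.3, the salt-and-pepper corruption regime; label flips on uniform binary
features are exactly per-pixel salt-and-pepper noise on the ideal output).

What these tables do and do not show. With no noise and all planted
realizations observed at least twice, the planted subset has cost exactly 0.
Under noise, every minimum-cost subset still *contains* the planted parity
features (dropping one makes the label conditionally uniform), and this
containment recovery is what the tests assert. Exact recovery of the
planted subset as the unique argmin is **not** a property of the plug-in
estimator on uniform features: each additional noise feature halves the
per-cell sample counts and the plug-in entropy's downward bias grows with
the number of cells, so supersets of the planted subset are systematically
favoured until the singleton-penalty regime (`t ≲ cells`) pushes costs
toward 1. Relatedly, the expected cost is not monotone in the number of
added noise features — it dips before the penalty takes over. Real
window-operator data, with strongly correlated features, need not behave
this way; passing tests here certify the search and the estimator's
definition, not estimator consistency.

## Oscillations

An *oscillation* is a consecutive-cardinality chain triple
`X₁ ⊂ X₂ ⊂ X₃` with `c(X₂) > max{c(X₁), c(X₃)}`; the per-element ratio is
the count divided by `2^n`. Subset-sum costs have none; finite-sample MCE
costs do, and in the generated tables the count grows steeply with the
number of features at fixed sample size — the pattern real instances show
as the search space outgrows the data. The count is *not* monotone in the
label-noise rate at fixed size: noise raises all conditional entropies
toward the flat top of the scale and at desk scale the aggregate trend over
noise is flat to slightly negative, so only the size trend is asserted.
Checking triples of consecutive cardinality is equivalent to checking all
chain triples for the U-curve property (a strict interior maximum on a
chain implies a strict local one); both the equivalence and the count are
validated against brute-force scans at n ≤ 6.

## The search-space store

The unexplored outer family starts as all `2^|S′|` words and shrinks by
interval removals, so it is held as a reduced ordered binary decision
diagram over the fixed coordinates: hash-consed nodes, membership by a
root-to-terminal walk, emptiness as identity with the false terminal,
interval removal as conjunction with the negated interval cube (built
directly, no general negation), exact model counting for sizes, and
uniform member sampling by count-weighted descent — the seeded random
`pop` the walk uses. Only this fragment of BDD algebra is implemented.
The explored set E is an explicit Python set (it only ever holds walked
elements) from which interval removals also delete. Behavioral equivalence
with an explicit set is enforced by randomized-history oracle tests.

## Numerical and design choices

* Bit convention: leftmost string digit = lexicographically first feature;
  masks store feature i at bit i. The string form is canonical in logs and
  reports.
* Minima sets are collected by exact equality with the best evaluated
  value; the 1e-12 relative tolerance guards only strict pruning/ordering
  decisions.
* Degenerate inputs: `p = 1` makes every inner lattice a singleton and the
  search still runs; `n = 1` compares `c(∅)` and `c(S)` directly; dimension
  0 stores hold exactly the empty word.
* Problem sizes in the test and reproduction runs — 200 instances at
  n ∈ 4..12 for optimality/soundness, 50 instances at n = 30 for the
  suboptimal regime, 1000 store histories at width ≤ 10, oscillation scans
  at n ≤ 7 — are chosen so each claim is exercised at full strength while a
  complete run stays in the minutes range on one core.

## Known limitations

* UBB here is a reconstruction from its defining properties (index-ordered
  spanning-tree DFS with dominance cuts); only optimality on U-decomposable
  costs is promised, not call-count parity with other published
  implementations.
* On non-U-decomposable costs PUCS returns the minimum over what it
  evaluated — an upper bound on the global minimum; with `base="es"` and
  `p = 1` it degrades gracefully to exhaustive search.
* No classifier-in-the-loop (wrapper-error) cost functions, and no
  genetic/best-first baselines; benchmark comparisons are restricted to the
  implemented algorithms.
* Wall-clock numbers in benchmark reports are recorded for orientation and
  never asserted: they are hardware-bound.
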