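# ucurve

Feature selection by Boolean-lattice search with U-curve pruning.

In classifier design, feature selection asks for a subset `X ⊆ S` of
features minimizing a cost function `c : P(S) → R≥0`. When the costs along
every chain `∅ ⊆ {s₁} ⊆ … ⊆ S` of the Boolean lattice `(P(S), ⊆)` describe a
U-shaped curve — `X₁ ⊆ X₂ ⊆ X₃ ⇒ c(X₂) ≤ max{c(X₁), c(X₃)}` — the
minimization is the *U-curve problem*. It is NP-hard (the cost
`c(X) = |t − Σ_{x∈X} w_x|` embeds subset sum), but the U-curve structure
licenses sound pruning of whole lattice intervals.

The package implements a parallelizable partitioned search (PUCS): pick a
fixed set `S′ ⊆ S` with `|S′| = ⌈p·n⌉`; each element `X` of the outer
lattice `P(S′)` anchors an inner lattice `{X ∪ Y : Y ⊆ S′̄}`, and the
`2^|S′|` inner lattices partition `P(S)`. A walk over the outer lattice
compares inner-lattice floors `c(X)` and ceilings `c(X ∪ S′̄)` of adjacent
elements: for `X ⊂ Y`,

* `c(X) < c(Y)` ⇒ discard the interval `[Y, S]`;
* `c(X ∪ S′̄) > c(Y ∪ S′̄)` ⇒ discard `[∅, X ∪ S′̄]`.

Surviving inner lattices are solved independently (the parallel region) —
recursively up to depth `l`, then by a pluggable base algorithm: exhaustive
search (ES), U-curve branch and bound (UBB, optimal on U-decomposable
costs), or greedy sequential selection (SFS / floating SFFS). Work is
reported as distinct cost-function calls via a memoizing evaluation ledger.

Cost functions included:

* **subset-sum** — `|t − Σ w|`, the hard-instance generator: provably
  U-decomposable, optimum 0 exactly when some subset hits the target;
* **penalized mean conditional entropy (MCE)** — for discrete labelled
  samples, `c(X) = N/t + Σ_{x: count(x) ≥ 2} Ĥ(Y|X=x)·count(x)/t`, where
  realizations observed once are charged the maximal entropy (log base
  `|L|`, so costs live in `[0, 1]`);
* explicit cost tables for hand-crafted fixtures.

The search-space store holding the unexplored outer family is a reduced
ordered binary decision diagram, so the initial family of `2^|S′|` words is
never materialized; interval removal is a conjunction with a negated cube.

## Worked example

```
$ ucurve generate subset-sum --n 10 --seed 42 --out inst.json
wrote subset-sum instance (n=10, target=228) to inst.json

$ ucurve select --data inst.json --cost subset-sum --algorithm pucs \
      --seed 7 --output report.json
best cost: 0
best subsets: 0101010010, 1000110110, 1100101110, 0001011110, 0000110111, 0100101111
cost function calls: 615
report written to report.json
```

The instance draws ten weights and target `t = 228`; the search finds six
subsets whose weights sum exactly to the target (best cost 0 = perfect
subset-sum certificates), evaluating 615 of the 1024 possible subsets — the
remaining 409 were discarded by recorded pruning events (five fired rules in
`report.json`). Subsets print as bit strings whose leftmost digit is the
lexicographically first feature (`w00`).

The same interface drives entropy-based selection on discrete sample tables
(`--cost mce`, whitespace-separated `.dat` or CSV with a `label` column),
oscillation counting (`ucurve oscillations`) and benchmark campaigns
(`ucurve benchmark --config bench.yaml`). The library surface mirrors the
CLI: `pucs_search`, `exhaustive_search`, `ubb_search`, `sfs_search`,
`sffs_search`, `gen_subset_sum_instance`, `gen_mce_dataset`,
`count_oscillations`, `run_benchmark`.

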