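"""Benchmark harness: run selection algorithms over generated instances and
tabulate best cost, distinct cost-function calls, wall time and — when an
exhaustive oracle is feasible — whether the global optimum was hit."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .algorithms import (
    ENUMERATION_GUARD,
    exhaustive_search,
    get_base_algorithm,
)
from .lattice import CostFunction, EvaluationLedger, GroundSet, cost_eq
from .pucs import PUCSParams, default_params, pucs_search
from .synth import gen_subset_sum_instance


def run_algorithm(name: str, ground: GroundSet, cost: CostFunction, *,
                  p: float | None = None, l: int = 1, base: str | None = None,
                  seed: int = 0, workers: int = 1, fixed=None,
                  force: bool = False):
    """Run one selection algorithm; returns (minima, best_cost, ledger, extra).

    ``name`` is "pucs" or a base algorithm ("es", "ubb", "sfs", "sffs").
    For PUCS, unspecified p/base fall back to the instance-size defaults.
    """
    name = name.lower()
    if name == "pucs":
        defaults = default_params(ground.n)
        params = PUCSParams(
            p=defaults.p if p is None else p,
            l=l,
            base=defaults.base if base is None else base,
            seed=seed,
            workers=workers,
            fixed=tuple(fixed) if fixed else None,
        )
        res = pucs_search(ground, cost, params)
        extra = {"events": res.events, "partition": res.partition,
                 "params": params, "survivors": res.survivors}
        return res.minima, res.best_cost, res.ledger, extra
    algo = get_base_algorithm(name)
    ledger = EvaluationLedger()
    kwargs = {"force": True} if (force and name in ("es", "ubb")) else {}
    result = algo(ground, cost, ledger, **kwargs)
    return result.minima, result.best_cost, result.ledger, {}


@dataclass(frozen=True)
class BenchRow:
    algorithm: str
    instance: int
    n: int
    best_cost: float
    calls: int
    time_sec: float
    optimal_hit: bool | None   # None when the oracle did not run


@dataclass
class BenchmarkReport:
    """Per (algorithm, instance) outcomes plus per-algorithm summaries."""

    rows: list = field(default_factory=list)

    def best_solution_proportion(self) -> dict:
        """Fraction of instances on which each algorithm matched the best
        solution found by any benchmarked algorithm (the head-to-head
        comparison used for suboptimal regimes)."""
        by_instance: dict = {}
        for r in self.rows:
            key = (r.n, r.instance)
            by_instance.setdefault(key, []).append(r)
        hits: dict = {}
        totals: dict = {}
        for group in by_instance.values():
            best = min(r.best_cost for r in group)
            for r in group:
                totals[r.algorithm] = totals.get(r.algorithm, 0) + 1
                if cost_eq(r.best_cost, best):
                    hits[r.algorithm] = hits.get(r.algorithm, 0) + 1
        return {a: hits.get(a, 0) / totals[a] for a in totals}

    def optimal_hit_proportion(self) -> dict:
        out: dict = {}
        for r in self.rows:
            if r.optimal_hit is None:
                continue
            n_hit, n_tot = out.get(r.algorithm, (0, 0))
            out[r.algorithm] = (n_hit + int(r.optimal_hit), n_tot + 1)
        return {a: h / t for a, (h, t) in out.items()}

    def to_tsv(self, path) -> None:
        lines = ["algorithm\tinstance\tn\tbest_cost\tcalls\ttime_sec\toptimal_hit"]
        for r in self.rows:
            hit = "" if r.optimal_hit is None else str(int(r.optimal_hit))
            lines.append(
                f"{r.algorithm}\t{r.instance}\t{r.n}\t{r.best_cost}"
                f"\t{r.calls}\t{r.time_sec:.6f}\t{hit}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path) -> None:
        payload = {
            "rows": [asdict(r) for r in self.rows],
            "best_solution_proportion": self.best_solution_proportion(),
            "optimal_hit_proportion": self.optimal_hit_proportion(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_benchmark(config: dict) -> BenchmarkReport:
    """Run the benchmark described by ``config``.

    Config keys: ``sizes`` (list of n), ``instances_per_size``, ``seed``,
    ``algorithms`` (list of {name, p?, l?, base?, workers?}), ``oracle``
    ("auto" runs an exhaustive check whenever n permits, "never" skips it).
    """
    sizes = list(config.get("sizes", [10]))
    count = int(config.get("instances_per_size", 10))
    seed = int(config.get("seed", 0))
    algorithms = config.get("algorithms", [{"name": "pucs"}])
    oracle_mode = config.get("oracle", "auto")

    report = BenchmarkReport()
    for n in sizes:
        for i in range(count):
            inst_seed = np.random.SeedSequence((seed, int(n), i))
            inst = gen_subset_sum_instance(int(n), np.random.default_rng(inst_seed))
            ground = inst.ground
            cost = inst.cost()
            oracle_best = None
            if oracle_mode == "auto" and n <= ENUMERATION_GUARD:
                oracle_best = exhaustive_search(ground, cost).best_cost
            for spec in algorithms:
                spec = dict(spec)
                name = spec.pop("name")
                t0 = time.perf_counter()
                _, best_cost, ledger, _ = run_algorithm(
                    name, ground, cost, seed=seed + i, **spec
                )
                elapsed = time.perf_counter() - t0
                hit = None if oracle_best is None else cost_eq(best_cost, oracle_best)
                report.rows.append(BenchRow(
                    algorithm=_label(name, spec),
                    instance=i,
                    n=int(n),
                    best_cost=best_cost,
                    calls=ledger.distinct_calls,
                    time_sec=elapsed,
                    optimal_hit=hit,
                ))
    return report


def _label(name: str, spec: dict) -> str:
    if name.lower() == "pucs" and spec.get("base"):
        return f"pucs({spec['base']})"
    return name.lower()
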