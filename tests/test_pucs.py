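"""Partitioned U-curve search: partition geometry, the pruning walk,
inner solving, optimality and the parallel contract."""

import numpy as np
import pytest

from ucurve import (
    AdjacencyCase,
    EvaluationLedger,
    FeatureSet,
    GroundSet,
    Partition,
    PUCSParams,
    adjacency_case,
    default_params,
    exhaustive_search,
    explicit_table_cost,
    gen_subset_sum_instance,
    make_partition,
    outer_walk,
    probe_costs,
    pucs_search,
)
from ucurve.lattice import FunctionCost
from ucurve.pucs import WalkState
from ucurve.store import SubsetFamilyStore


class TestPartition:
    def test_fixed_set_size_is_ceiling(self, rng_factory):
        ground = GroundSet("abcde")
        part = make_partition(ground, 0.5, rng_factory(0))
        assert part.dim == 3  # ⌈2.5⌉

    def test_fixing_two_of_five_gives_four_inner_lattices(self):
        ground = GroundSet("abcde")
        part = Partition(ground, fixed_idx=(0, 1))
        assert part.n_inner_lattices == 4

    def test_p_one_degenerate_inner_lattices(self, rng_factory):
        ground = GroundSet("abcd")
        part = make_partition(ground, 1.0, rng_factory(0))
        assert part.dim == 4
        assert part.free_idx == ()
        assert list(part.inner_members(0b0101)) == [0b0101]

    def test_p_out_of_range_rejected(self, rng_factory):
        ground = GroundSet("ab")
        for p in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                make_partition(ground, p, rng_factory(0))

    def test_explicit_fixed_override(self):
        ground = GroundSet("abcde")
        part = make_partition(ground, 0.5, fixed=["b", "d"])
        assert part.fixed.names() == {"b", "d"}

    def test_inner_lattices_partition_power_set(self, rng_factory):
        # pairwise disjoint, union exhaustive, by enumeration
        for n, p in ((6, 0.5), (8, 0.3), (5, 1.0)):
            ground = GroundSet([f"f{i}" for i in range(n)])
            part = make_partition(ground, p, rng_factory(n))
            seen = []
            for word in range(1 << part.dim):
                seen.extend(part.inner_members(word))
            assert len(seen) == 1 << n
            assert len(set(seen)) == 1 << n

    def test_embed_restrict_round_trip(self, rng_factory):
        ground = GroundSet("abcdefg")
        part = make_partition(ground, 0.4, rng_factory(1))
        for word in range(1 << part.dim):
            assert part.restrict_outer(part.embed_outer(word)) == word


class TestProbes:
    def test_anchor_empty_probes_bottom_and_top(self, rng_factory):
        inst = gen_subset_sum_instance(5, rng_factory(0))
        ground, cost = inst.ground, inst.cost()
        part = make_partition(ground, 0.4, rng_factory(1))
        ledger = EvaluationLedger()
        floor, ceiling = probe_costs(0, part, cost, ledger)
        assert floor == cost.evaluate_mask(0)
        assert ceiling == cost.evaluate_mask(part.free.mask)

    def test_repeat_probe_no_new_calls(self, rng_factory):
        inst = gen_subset_sum_instance(6, rng_factory(0))
        part = make_partition(inst.ground, 0.5, rng_factory(1))
        ledger = EvaluationLedger()
        probe_costs(1, part, inst.cost(), ledger)
        before = ledger.distinct_calls
        probe_costs(1, part, inst.cost(), ledger)
        assert ledger.distinct_calls == before

    def test_probes_match_direct_evaluation(self, rng_factory):
        inst = gen_subset_sum_instance(7, rng_factory(4))
        ground, cost = inst.ground, inst.cost()
        part = make_partition(ground, 0.5, rng_factory(2))
        ledger = EvaluationLedger()
        for word in range(1 << part.dim):
            floor, ceiling = probe_costs(word, part, cost, ledger)
            anchor = part.embed_outer(word)
            assert floor == cost.evaluate_mask(anchor)
            assert ceiling == cost.evaluate_mask(anchor | part.free.mask)


class TestAdjacencyCase:
    # probes are (floor, ceiling) pairs
    def test_upward_ceiling_fires_corollary_and_moves(self):
        # walking up with a higher ceiling at X: the lower interval [∅, X∪S′¯]
        # is discarded and the walk advances to Y
        case = adjacency_case(0b00, 0b01, (5, 9), (5, 7))
        assert case is AdjacencyCase.PRUNE_LOWER_MOVE

    def test_upward_floor_fires_proposition_and_stays(self):
        case = adjacency_case(0b00, 0b01, (2, 7), (5, 7))
        assert case is AdjacencyCase.PRUNE_UPPER_STAY

    def test_downward_floor_fires_proposition_and_moves(self):
        case = adjacency_case(0b01, 0b00, (5, 7), (2, 7))
        assert case is AdjacencyCase.PRUNE_UPPER_MOVE

    def test_downward_ceiling_fires_corollary_and_stays(self):
        case = adjacency_case(0b01, 0b00, (5, 7), (5, 9))
        assert case is AdjacencyCase.PRUNE_LOWER_STAY

    def test_equal_probes_move_without_pruning(self):
        assert adjacency_case(0b10, 0b11, (4, 4), (4, 4)) is AdjacencyCase.MOVE

    def test_branch_order_ceiling_before_floor_upward(self):
        # both conditions hold; the ceiling test is evaluated first
        case = adjacency_case(0b00, 0b01, (1, 9), (5, 7))
        assert case is AdjacencyCase.PRUNE_LOWER_MOVE

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError, match="not adjacent"):
            adjacency_case(0b00, 0b11, (0, 0), (0, 0))


class TestOuterWalk:
    def test_single_fixed_point_explores_at_most_two(self, rng_factory):
        inst = gen_subset_sum_instance(5, rng_factory(0))
        ground, cost = inst.ground, inst.cost()
        part = make_partition(ground, 0.2, rng_factory(1))  # ⌈1⌉ fixed point
        assert part.dim == 1
        ledger = EvaluationLedger()
        walk = outer_walk(part, cost, ledger, np.random.default_rng(0))
        assert len(set(walk.visit_order)) <= 2

    def test_minimum_inner_lattice_never_pruned(self, rng_factory):
        # on U-decomposable instances no outer element whose inner lattice
        # holds the global minimum may be pruned
        for seed in range(20):
            n = 6 + seed % 5
            inst = gen_subset_sum_instance(n, rng_factory(seed))
            ground, cost = inst.ground, inst.cost()
            es = exhaustive_search(ground, cost)
            part = make_partition(ground, 0.5, rng_factory(1000 + seed))
            ledger = EvaluationLedger()
            walk = outer_walk(part, cost, ledger, np.random.default_rng(seed))
            survivor_words = set(walk.survivors)
            for fs in es.minima:
                assert part.restrict_outer(fs.mask) in survivor_words

    def test_every_outer_element_explored_or_pruned(self, rng_factory):
        inst = gen_subset_sum_instance(8, rng_factory(3))
        ground, cost = inst.ground, inst.cost()
        part = make_partition(ground, 0.5, rng_factory(4))
        ledger = EvaluationLedger()
        walk = outer_walk(part, cost, ledger, np.random.default_rng(1))
        covered = set(walk.survivors)
        for e in walk.events:
            for w in range(1 << part.dim):
                if e.outer_lower & w == e.outer_lower and w & e.outer_upper == w:
                    covered.add(w)
        assert covered == set(range(1 << part.dim))


class TestPUCSSearch:
    def test_n_equals_one_compares_both_subsets(self):
        inst_weights = {"a": 3}
        from ucurve import SubsetSumInstance
        inst = SubsetSumInstance(weights=inst_weights, target=3)
        res = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=0))
        assert res.best_cost == 0
        assert res.best_subset.bits == "1"
        assert set(res.ledger.computed) == {0, 1}

    def test_planted_solution_reaches_zero(self, rng_factory):
        # instance with a subset summing exactly to the target
        rng = rng_factory(10)
        weights = {f"w{i}": int(w) for i, w in enumerate(rng.integers(1, 50, 8))}
        chosen = ["w1", "w3", "w4"]
        target = sum(weights[w] for w in chosen)
        from ucurve import SubsetSumInstance
        inst = SubsetSumInstance(weights=weights, target=target)
        res = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=2))
        assert res.best_cost == 0

    def test_matches_exhaustive_minimum(self, rng_factory):
        for seed in range(40):
            n = 4 + seed % 9
            inst = gen_subset_sum_instance(n, rng_factory(3000 + seed))
            ground, cost = inst.ground, inst.cost()
            es = exhaustive_search(ground, cost)
            res = pucs_search(ground, cost, PUCSParams(seed=seed))
            assert res.best_cost == es.best_cost
            assert set(res.minima) <= set(es.minima)

    def test_reproducible_for_fixed_seed(self, rng_factory):
        inst = gen_subset_sum_instance(9, rng_factory(5))
        a = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=9))
        b = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=9))
        assert a.best_cost == b.best_cost
        assert [f.bits for f in a.minima] == [f.bits for f in b.minima]
        assert a.n_calls == b.n_calls

    def test_worker_count_invariance(self, rng_factory):
        inst = gen_subset_sum_instance(10, rng_factory(6))
        results = [
            pucs_search(inst.ground, inst.cost(),
                        PUCSParams(seed=4, workers=w))
            for w in (1, 2)
        ]
        costs = {r.best_cost for r in results}
        assert len(costs) == 1
        minima_sets = [set(f.bits for f in r.minima) for r in results]
        assert minima_sets[0] == minima_sets[1]
        assert len({r.n_calls for r in results}) == 1

    def test_recursion_depth_preserves_optimality(self, rng_factory):
        for seed in range(10):
            inst = gen_subset_sum_instance(8, rng_factory(400 + seed))
            r1 = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=seed, l=1))
            r2 = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=seed, l=2))
            assert r1.best_cost == r2.best_cost

    def test_p_one_degenerate_still_runs(self, rng_factory):
        inst = gen_subset_sum_instance(6, rng_factory(8))
        es = exhaustive_search(inst.ground, inst.cost())
        res = pucs_search(inst.ground, inst.cost(), PUCSParams(seed=0, p=1.0))
        assert res.best_cost == es.best_cost

    def test_pruned_elements_never_beat_returned_best(self, rng_factory):
        for seed in range(15):
            n = 6 + seed % 5
            inst = gen_subset_sum_instance(n, rng_factory(700 + seed))
            ground, cost = inst.ground, inst.cost()
            res = pucs_search(ground, cost, PUCSParams(seed=seed))
            for m in range(1 << n):
                if m in res.ledger.computed:
                    continue
                if any(e.covers_mask(m) for e in res.events):
                    assert cost.evaluate_mask(m) >= res.best_cost

    def test_oscillating_cost_internally_consistent(self):
        # a non-U-decomposable explicit table: PUCS must still return the
        # minimum over its own ledger, bounded below by the true optimum
        values = {
            "000": 4, "100": 9, "010": 1, "001": 6,
            "110": 0, "101": 8, "011": 7, "111": 2,
        }
        cost = explicit_table_cost(values)
        ground = cost.ground
        true_min = min(values.values())
        res = pucs_search(ground, cost, PUCSParams(seed=1))
        assert res.best_cost == min(res.ledger.computed.values())
        assert res.best_cost >= true_min
        # exhaustive leaf with p=1 recovers the optimum despite oscillations
        full = pucs_search(ground, cost, PUCSParams(seed=1, p=1.0, base="es"))
        assert full.best_cost == true_min

    def test_default_params_follow_instance_size(self):
        small = default_params(10)
        big = default_params(40)
        assert (small.p, small.base) == (0.5, "ubb")
        assert big.base == "sfs"
        assert big.p == pytest.approx(10 / 40)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PUCSParams(p=0)
        with pytest.raises(ValueError):
            PUCSParams(l=0)
        with pytest.raises(ValueError):
            PUCSParams(base="nope")
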