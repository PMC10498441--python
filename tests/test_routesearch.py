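import pytest
from hypothesis import given, settings, strategies as st

from retroplan.chemdb import FixedReaction, FixedReactionDB
from retroplan.fixtures import NetworkSpec, make_building_blocks, make_synthetic_network
from retroplan.routesearch import (
    CostModel,
    ReactionEdge,
    SearchParams,
    Subnetwork,
    brute_force_k_best,
    build_subnetwork,
    constrained_search,
    effective_yield,
    group_strategies,
    k_best_routes,
    reaction_cost,
    routes_document,
)

from conftest import assert_repetition_free


class TestCostRules:
    def test_fixed_yield_passthrough(self):
        e = ReactionEdge("r", ("A",), "B", "fixed", yield_=0.82)
        assert effective_yield(e, CostModel()) == 0.82

    def test_fixed_missing_yield_defaults_to_half(self):
        e = ReactionEdge("r", ("A",), "B", "fixed")
        assert effective_yield(e, CostModel()) == 0.50

    def test_generated_yield_capped_at_seventy_percent(self):
        e = ReactionEdge("r", ("A",), "B", "generated", score=0.90)
        assert effective_yield(e, CostModel()) == 0.70
        e2 = ReactionEdge("r2", ("A",), "B", "generated", score=0.45)
        assert effective_yield(e2, CostModel()) == 0.45

    def test_bad_reported_yield_is_a_data_error(self):
        e = ReactionEdge("r", ("A",), "B", "fixed", yield_=1.4)
        with pytest.raises(ValueError):
            effective_yield(e, CostModel())

    @pytest.mark.parametrize("costs,y,expected", [
        ([2.0, 3.0], 0.5, 10.0),
        ([1.0], 1.0, 1.0),
        ([4.0], 0.5, 8.0),
    ])
    def test_reaction_cost(self, costs, y, expected):
        assert reaction_cost(costs, y, CostModel()) == pytest.approx(expected)

    def test_reaction_cost_overhead(self):
        cm = CostModel(per_reaction_overhead=1.5)
        assert reaction_cost([2.0], 1.0, cm) == pytest.approx(3.5)

    def test_nonpositive_yield_rejected(self):
        with pytest.raises(ValueError):
            reaction_cost([1.0], 0.0, CostModel())


class TestWorkedExamples:
    def test_chain_cost(self, worked):
        ex = worked["chain"]
        routes = k_best_routes(ex.net, ex.target, SearchParams(k=5))
        assert [r.cost for r in routes] == pytest.approx([8.0])
        assert routes[0].leaves == ("BB",)
        assert routes[0].n_reactions == 2

    def test_diamond_costs_ordered(self, worked):
        ex = worked["diamond"]
        routes = k_best_routes(ex.net, ex.target, SearchParams(k=2))
        assert [r.cost for r in routes] == pytest.approx([8.0, 10.0])
        assert routes[0].final_reaction == "r_b"

    def test_cycle_terminates_repetition_free(self, worked):
        ex = worked["cycle"]
        routes = k_best_routes(ex.net, ex.target, SearchParams(k=5))
        assert [r.cost for r in routes] == pytest.approx([8.0])
        for r in routes:
            assert_repetition_free(r, ex.net)

    def test_k_exceeding_existing_routes(self, worked):
        ex = worked["threeroutes"]
        routes = k_best_routes(ex.net, ex.target, SearchParams(k=5))
        assert len(routes) == 3
        assert [r.cost for r in routes] == pytest.approx(sorted(ex.expected_costs))


class TestSubnetwork:
    def make_generated(self):
        return [
            ReactionEdge("G0", ("X",), "T", "generated", score=0.6),
            ReactionEdge("G1", ("Y",), "X", "generated", score=0.6),
            ReactionEdge("G2", ("Z",), "W", "generated", score=0.6),  # unreachable
        ]

    def test_unreachable_reactions_excluded(self):
        sub = build_subnetwork("T", self.make_generated(), None, None, 10)
        assert "G2" not in sub.reactions
        assert set(sub.reactions) == {"G0", "G1"}

    def test_max_depth_one_keeps_only_target_producers(self):
        sub = build_subnetwork("T", self.make_generated(), None, None, 1)
        assert set(sub.reactions) == {"G0"}

    def test_fixed_reactions_stitched_under_generated_leaf(self):
        fdb = FixedReactionDB([
            FixedReaction(("U",), "Y", 0.9),
            FixedReaction(("V",), "U", 0.8),
        ])
        bbs = make_building_blocks({"CCO": 1.0})
        sub = build_subnetwork("T", self.make_generated(), fdb, None, 10)
        fixed = [r for r in sub.reactions.values() if r.origin == "fixed"]
        assert {f.product for f in fixed} == {"Y", "U"}

    def test_no_producers_gives_single_node_network(self):
        sub = build_subnetwork("T", [], None, None, 10)
        assert list(sub.compounds) == ["T"]
        assert k_best_routes(sub, "T", SearchParams(k=3)) == []


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.sampled_from([1, 3, 5]))
    def test_matches_brute_force(self, seed, k):
        net, target, _ = make_synthetic_network(NetworkSpec(seed=seed))
        fast = k_best_routes(net, target, SearchParams(k=k))
        slow = brute_force_k_best(net, target, k)
        assert [r.cost for r in fast] == pytest.approx(
            [r.cost for r in slow], rel=1e-9)
        assert [r.reaction_set for r in fast] == [r.reaction_set for r in slow]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sorted_bounded_superadditive(self, seed):
        net, target, prices = make_synthetic_network(NetworkSpec(seed=seed))
        routes = k_best_routes(net, target, SearchParams(k=5))
        assert len(routes) <= 5
        costs = [r.cost for r in routes]
        assert costs == sorted(costs)
        for r in routes:
            leaf_sum = sum(prices[leaf] for leaf in r.leaves)
            assert r.cost >= leaf_sum - 1e-9
            assert_repetition_free(r, net)

    def test_brute_force_refuses_large_networks(self):
        net, target, _ = make_synthetic_network(
            NetworkSpec(n_compounds=20, n_reactions=40, seed=0))
        with pytest.raises(ValueError, match="too large"):
            brute_force_k_best(net, target, 3)


class TestConstraints:
    def test_avoid_prunes_cheaper_branch(self, worked):
        ex = worked["diamond"]
        routes = constrained_search(
            ex.net, ex.target, SearchParams(k=2, avoid=frozenset({"r_b"})))
        assert [r.cost for r in routes] == pytest.approx([10.0])
        assert all("r_b" not in r.reaction_set for r in routes)

    def test_avoid_compound(self, worked):
        ex = worked["diamond"]
        routes = constrained_search(
            ex.net, ex.target, SearchParams(k=2, avoid=frozenset({"B"})))
        assert [r.cost for r in routes] == pytest.approx([10.0])

    def test_keep_selects_route_through_compound(self, worked):
        ex = worked["threeroutes"]
        routes = constrained_search(
            ex.net, ex.target, SearchParams(k=5, keep=frozenset({"X"})))
        assert len(routes) == 1
        assert "X" in routes[0].compounds()
        assert routes[0].cost == pytest.approx(6.0)

    def test_keep_avoid_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="overlap"):
            SearchParams(k=1, keep=frozenset({"c"}), avoid=frozenset({"c"}))


class TestPartialRoutes:
    def make_net(self):
        net = Subnetwork()
        net.add_compound("BB", True, 2.0)
        net.add_compound("OPEN")  # no supplier, no producing reaction
        net.add_reaction(ReactionEdge("r1", ("OPEN", "BB"), "T", "fixed", yield_=1.0))
        net.add_reaction(ReactionEdge("r2", ("BB",), "T", "fixed", yield_=0.1))
        return net

    def test_disabled_by_default(self):
        net = self.make_net()
        routes = k_best_routes(net, "T", SearchParams(k=5))
        assert [r.is_partial for r in routes] == [False]

    def test_partials_flagged_and_penalized_after_complete(self):
        net = self.make_net()
        routes = k_best_routes(net, "T", SearchParams(k=5, allow_partial=True))
        assert len(routes) == 2
        assert [r.is_partial for r in routes] == [False, True]
        assert routes[0].cost < routes[1].cost
        assert routes[1].cost >= CostModel().partial_leaf_penalty
        assert "OPEN" in routes[1].leaves

    def test_unreachable_without_partials_gives_empty(self):
        net = Subnetwork()
        net.add_compound("OPEN")
        net.add_reaction(ReactionEdge("r1", ("OPEN",), "T", "fixed", yield_=1.0))
        assert k_best_routes(net, "T", SearchParams(k=3)) == []
        partial = k_best_routes(net, "T", SearchParams(k=3, allow_partial=True))
        assert len(partial) == 1 and partial[0].is_partial


class TestStrategies:
    def test_grouping_and_order(self, worked):
        ex = worked["threeroutes"]
        routes = k_best_routes(ex.net, ex.target, SearchParams(k=5))
        strategies = group_strategies(routes)
        assert len(strategies) == 3  # all final reactions differ
        assert [s.best_cost for s in strategies] == sorted(
            s.best_cost for s in strategies)

    def test_shared_final_reaction_grouped(self):
        net = Subnetwork()
        net.add_compound("A", True, 1.0)
        net.add_compound("B", True, 2.0)
        net.add_reaction(ReactionEdge("p1", ("A",), "X", "fixed", yield_=1.0))
        net.add_reaction(ReactionEdge("p2", ("B",), "X", "fixed", yield_=1.0))
        net.add_reaction(ReactionEdge("fin", ("X",), "T", "fixed", yield_=1.0))
        net.add_reaction(ReactionEdge("alt", ("B",), "T", "fixed", yield_=0.1))
        routes = k_best_routes(net, "T", SearchParams(k=5))
        strategies = group_strategies(routes)
        assert len(strategies) == 2
        sizes = sorted(len(s.routes) for s in strategies)
        assert sizes == [1, 2]
        for s in strategies:
            assert all(r.final_reaction == s.final_reaction for r in s.routes)

    def test_empty_routes_give_empty_strategies(self):
        assert group_strategies([]) == []


def test_routes_document_schema(worked):
    ex = worked["chain"]
    params = SearchParams(k=1)
    routes = k_best_routes(ex.net, ex.target, params)
    doc = routes_document(ex.target, params, group_strategies(routes), ex.net)
    assert doc["target"] == "T"
    route = doc["strategies"][0]["routes"][0]
    assert route["cost"] == pytest.approx(8.0)
    assert [r["id"] for r in route["reactions"]] == ["r1", "r2"]  # dependency order
    assert route["leaves"][0]["price"] == 2.0
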