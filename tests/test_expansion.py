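import pytest

from retroplan.chemdb import FixedReaction, FixedReactionDB
from retroplan.expansion import (
    ALGORITHMS,
    ExpansionConfig,
    compound_priority,
    expand,
    reaction_priority,
    terminal_status,
)
from retroplan.feasibility import ClassifierStore
from retroplan.fixtures import make_building_blocks
from retroplan.routesearch import SearchParams, build_subnetwork, k_best_routes

from conftest import assert_repetition_free


class TestTerminalStatus:
    def test_purchasable_takes_precedence(self):
        bbs = make_building_blocks({"CCO": 1.0})
        fdb = FixedReactionDB([FixedReaction(("CC=O",), "CCO", 0.9)])
        assert terminal_status("CCO", bbs, fdb) == "purchasable"

    def test_fixed_product_is_known_synthesizable(self):
        fdb = FixedReactionDB([FixedReaction(("CC=O",), "CCO", 0.9)])
        assert terminal_status("CCO", None, fdb) == "known_synthesizable"

    def test_neither_is_open(self):
        assert terminal_status("CCO", None, None) == "open"


class TestPriorities:
    @pytest.mark.parametrize("smi,depth,expected", [
        ("c1ccccc1", 1, 6.0),
        ("c1ccccc1", 2, 6 * 2 ** 1.1),
        ("OCc1ccc(O)cc1", 3, 9 * 3 ** 1.1),
    ])
    def test_compound_priority(self, smi, depth, expected):
        assert compound_priority(smi, depth, 1.1) == pytest.approx(expected)

    def test_compound_priority_values(self):
        assert compound_priority("c1ccccc1", 2, 1.1) == pytest.approx(12.861, abs=0.01)

    def test_reaction_priority_is_max_reactant(self):
        # 5 and 9 heavy atoms at depth 1 -> 9.0; depth 2 -> 9 * 2**1.1
        r = ("CCCCC", "CCCCCCCCC")
        assert reaction_priority(r, 1, 1.1) == pytest.approx(9.0)
        assert reaction_priority(r, 2, 1.1) == pytest.approx(19.29, abs=0.01)
        assert reaction_priority(("CCCCC",), 1, 1.1) == pytest.approx(5.0)

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            compound_priority("C", 0)
        with pytest.raises(ValueError):
            reaction_priority(("C",), 0)


class TestExpand:
    def test_purchasable_target_generates_nothing(self, library, chem_target_bbs):
        _, bbs = chem_target_bbs
        net = expand("CC(=O)O", library, None, bbs, None, ExpansionConfig())
        assert net.generated_count == 0
        assert net.solved

    def test_zero_budget_generates_nothing(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        for algo in ALGORITHMS:
            net = expand(target, library, None, bbs, None,
                         ExpansionConfig(algorithm=algo, max_generated=0))
            assert net.generated_count == 0

    @pytest.mark.parametrize("algo", ALGORITHMS)
    @pytest.mark.parametrize("budget", [5, 17, 60])
    def test_budget_respected(self, library, chem_target_bbs, algo, budget):
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(algorithm=algo, max_generated=budget))
        assert net.generated_count <= budget
        assert len(net.reactions) == net.generated_count

    def test_all_kept_reactions_meet_threshold(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(max_generated=100))
        assert all(e.score >= 0.2 for e in net.reactions)

    def test_low_scores_are_rejected(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        store = ClassifierStore(default_score=0.1)  # below the 0.2 threshold
        net = expand(target, library, store, bbs, None,
                     ExpansionConfig(max_generated=100))
        assert net.generated_count == 0
        assert net.rejected_count > 0

    def test_single_amide_disconnection_fixture(self, library):
        # both reactants purchasable: one step solves the target
        bbs = make_building_blocks({"CC(=O)O": 1.0, "Nc1ccccc1": 2.0,
                                    "COC(=O)C": 1.0, "CO": 1.0})
        net = expand("CC(=O)Nc1ccccc1", library, None, bbs, None,
                     ExpansionConfig(algorithm="breadth_first", max_generated=50))
        assert net.solved
        amide = [e for e in net.reactions
                 if set(e.reactants) == {"CC(=O)O", "Nc1ccccc1"}]
        assert len(amide) == 1

    def test_invalid_target_raises(self, library):
        with pytest.raises(Exception):
            expand("not_a_smiles", library, None, None, None, ExpansionConfig())

    def test_multifragment_target_rejected(self, library):
        with pytest.raises(ValueError, match="single molecule"):
            expand("CC(=O)O.Nc1ccccc1", library, None, None, None,
                   ExpansionConfig())

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_deterministic(self, library, chem_target_bbs, algo):
        target, bbs = chem_target_bbs
        cfg = ExpansionConfig(algorithm=algo, max_generated=40)
        a = expand(target, library, None, bbs, None, cfg)
        b = expand(target, library, None, bbs, None, cfg)
        assert [e.rid for e in a.reactions] == [e.rid for e in b.reactions]
        assert [(e.reactants, e.product, e.template_id) for e in a.reactions] == \
               [(e.reactants, e.product, e.template_id) for e in b.reactions]

    def test_breadth_first_finds_shortest_route_first(self, library, chem_target_bbs):
        """The fixture admits 2-step and 4-step routes; with early stop the
        breadth-first network only contains shortest (2-step) routes."""
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(algorithm="breadth_first",
                                     max_generated=500, early_stop=True))
        assert net.solved
        sub = build_subnetwork(target, net.reactions, None, bbs, max_depth=10)
        routes = k_best_routes(sub, target, SearchParams(k=10))
        assert routes
        assert min(r.n_reactions for r in routes) == 2
        assert all(r.n_reactions == 2 for r in routes)

    def test_fixture_admits_two_and_four_step_routes(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(algorithm="breadth_first", max_generated=500))
        sub = build_subnetwork(target, net.reactions, None, bbs, max_depth=10)
        routes = k_best_routes(sub, target, SearchParams(k=20))
        lengths = {r.n_reactions for r in routes}
        assert 2 in lengths and 4 in lengths

    def test_best_first_reaction_solves_within_100(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(algorithm="best_first_reaction",
                                     max_generated=100))
        assert net.generated_count <= 100
        assert net.solved

    def test_routes_from_expansion_are_repetition_free(self, library, chem_target_bbs):
        target, bbs = chem_target_bbs
        net = expand(target, library, None, bbs, None,
                     ExpansionConfig(max_generated=200))
        sub = build_subnetwork(target, net.reactions, None, bbs, max_depth=10)
        for route in k_best_routes(sub, target, SearchParams(k=10)):
            assert_repetition_free(route, sub)

    def test_known_synthesizable_counts_as_terminal(self, library):
        # aniline is a product in the fixed DB, so it is not expanded
        fdb = FixedReactionDB(
            [FixedReaction(("O=[N+]([O-])c1ccccc1",), "Nc1ccccc1", 0.9)])
        bbs = make_building_blocks({"CC(=O)O": 1.0})
        net = expand("CC(=O)Nc1ccccc1", library, None, bbs, fdb,
                     ExpansionConfig(algorithm="breadth_first", max_generated=50))
        assert net.nodes["Nc1ccccc1"].status == "known_synthesizable"
        assert not net.nodes["Nc1ccccc1"].expanded
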