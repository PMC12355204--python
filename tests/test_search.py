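"""Search engine: budget accounting, solve semantics, route extraction."""

import math

import pytest

from tangoplan import (
    CostWeights,
    Molecule,
    Route,
    RouteNode,
    SearchConfig,
    TabularPolicy,
    extract_route,
    generate,
    is_constrained_solved,
    load_route,
    route_length,
    save_route,
    search,
)
from reference import (
    CountingPolicy,
    constrained_route_exists,
    min_route_cost,
    plain_best_first_trace,
)


def make_config(net, budget=100, k=25.0, c=0.0, **kwargs):
    return SearchConfig(
        expansion_budget=budget, cost_weights=CostWeights(k=k, c=c),
        building_blocks=net.building_blocks, enforced_sm=net.enforced_sm,
        **kwargs)


def tokens(*names):
    mols = [Molecule.token(n, heavy_atom_count=i + 2)
            for i, n in enumerate(names)]
    by_key = {m.smiles: m for m in mols}
    by_key.update({n: m for n, m in zip(names, mols)})
    return by_key


class TestDegenerateAndBudget:
    def test_target_is_sm(self):
        net = generate(depth=2, branching=1, decoy_rate=0.0, seed=0,
                       mode="abstract")
        config = make_config(net)
        result = search(net.enforced_sm, net.policy(), config)
        assert result.solved
        assert result.expansions_used == 0
        assert result.route.length == 0

    def test_budget_one_on_deep_problem(self):
        net = generate(depth=3, branching=1, decoy_rate=0.0, seed=0,
                       mode="abstract")
        policy = CountingPolicy(net.policy())
        result = search(net.target, policy, make_config(net, budget=1),
                        cost=net.oracle_cost())
        assert not result.solved
        assert result.expansions_used == 1 == policy.calls

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_policy_calls_equal_expansions(self, seed):
        net = generate(depth=4, branching=3, decoy_rate=0.4, seed=seed,
                       mode="real")
        policy = CountingPolicy(net.policy())
        result = search(net.target, policy, make_config(net, budget=50))
        assert policy.calls == result.expansions_used <= 50


class TestPlantedNetworks:
    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_solves_planted_route(self, seed):
        net = generate(depth=3, branching=2, decoy_rate=0.3, seed=seed,
                       mode="real")
        result = search(net.target, net.policy(), make_config(net, budget=60))
        assert result.solved
        assert result.expansions_used <= len(net.molecules)
        assert any(m == net.enforced_sm for m in result.route.leaves())
        assert all(m.smiles in net.building_blocks
                   for m in result.route.leaves())

    def test_route_replays_through_policy(self):
        net = generate(depth=4, branching=2, decoy_rate=0.3, seed=3,
                       mode="real")
        policy = net.policy()
        result = search(net.target, policy, make_config(net, budget=60))
        assert result.solved

        def check(node):
            if node.is_leaf:
                return
            keys = {p.precursor_key()
                    for p in policy.propose(node.molecule, top_n=100)}
            assert tuple(sorted(c.molecule.smiles
                                for c in node.children)) in keys
            for c in node.children:
                check(c)

        check(result.route.root)

    def test_trace_is_deterministic(self):
        net = generate(depth=4, branching=3, decoy_rate=0.4, seed=7,
                       mode="real")
        results = [search(net.target, net.policy(), make_config(net, budget=40))
                   for _ in range(2)]
        assert results[0].trace == results[1].trace
        assert results[0].route.to_json_dict() == results[1].route.to_json_dict()


class TestUnguidedReduction:
    @pytest.mark.parametrize("seed", range(10))
    def test_k0_trace_matches_reference_best_first(self, seed):
        """With guidance off, the engine must behave exactly like an
        unguided best-first search (independent reimplementation)."""
        net = generate(depth=3, branching=3, decoy_rate=0.4, seed=seed,
                       mode="real")
        budget = 25
        config = make_config(net, budget=budget, k=0.0,
                             stop_on_first_solve=False)
        ours = search(net.target, net.policy(), config)
        ref = plain_best_first_trace(net.target, net.policy(),
                                     config.building_blocks, budget)
        assert ours.trace == ref


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_best_route_cost_matches_enumeration(self, seed):
        net = generate(depth=4, branching=2, decoy_rate=0.5, seed=seed,
                       mode="real")
        assert len(net.molecules) <= 200
        config = make_config(net, budget=len(net.molecules) + 5, k=0.0,
                             stop_on_first_solve=False)
        result = search(net.target, net.policy(), config)
        best = extract_route(result.graph)
        assert best is not None
        assert best.cost == pytest.approx(min_route_cost(net))
        assert result.solved == constrained_route_exists(net)

    def test_unreachable_sm_reported_unsolved(self):
        net = generate(depth=3, branching=2, decoy_rate=0.0, seed=4,
                       mode="real")
        # sever the planted disconnection closest to sm*
        cut = {prod: [e for e in entries if not e[2].startswith("planted-1")]
               for prod, entries in net.reactions.items()}
        policy = TabularPolicy(cut, net.molecules)
        net.reactions = cut
        config = make_config(net, budget=len(net.molecules) + 5,
                             stop_on_first_solve=False)
        result = search(net.target, policy, config)
        assert not constrained_route_exists(net)
        assert not result.solved
        # the unconstrained problem may still be solvable via decoys
        assert result.unconstrained_solved == (min_route_cost(net) is not None)


class TestCycleHandling:
    def test_loop_proposals_discarded(self):
        mols = tokens("T", "B")
        table = {"tok:T": [(("tok:B",), 0.8, "r1")],
                 "tok:B": [(("tok:T",), 0.8, "r2")]}
        policy = TabularPolicy(table, mols)
        config = SearchConfig(expansion_budget=10,
                              building_blocks=frozenset(),
                              enforced_sm=mols["B"],
                              cost_weights=CostWeights(k=0.0))
        result = search(mols["T"], policy, config)
        # B -> T re-proposal is rejected; B becomes purchasable (it is sm*)
        assert result.solved
        assert result.route.length == 1


class TestRouteExtraction:
    def test_prefers_sm_route_even_at_higher_cost(self):
        mols = tokens("T", "A", "SM")
        table = {"tok:T": [(("tok:A",), 0.9, "cheap"),
                           (("tok:SM",), 0.5, "dear")]}
        policy = TabularPolicy(table, mols)
        config = SearchConfig(expansion_budget=5,
                              building_blocks=frozenset({"tok:A"}),
                              enforced_sm=mols["SM"],
                              cost_weights=CostWeights(k=0.0))
        result = search(mols["T"], policy, config)
        assert result.solved
        leaves = result.route.leaves()
        assert mols["SM"] in leaves
        cheap = extract_route(result.graph, prefer_sm=None)
        assert cheap.cost < result.route.cost

    def test_unsolved_graph_returns_none(self):
        mols = tokens("T")
        policy = TabularPolicy({}, mols)
        config = SearchConfig(expansion_budget=3,
                              building_blocks=frozenset(),
                              enforced_sm=Molecule.token("SM"),
                              cost_weights=CostWeights(k=0.0))
        result = search(mols["T"], policy, config)
        assert not result.solved and result.route is None


class TestRouteMetrics:
    @staticmethod
    def linear_chain(names):
        node = RouteNode(molecule=Molecule.token(names[-1]))
        for name in reversed(names[:-1]):
            node = RouteNode(molecule=Molecule.token(name), children=(node,))
        return node

    def test_convergent_route_length_is_longest_branch(self):
        # branches of 3 and 5 reactions, counting the shared root reaction
        left = self.linear_chain([f"L{i}" for i in range(3)])
        right = self.linear_chain([f"R{i}" for i in range(5)])
        root = RouteNode(molecule=Molecule.token("T"), children=(left, right))
        route = Route(root=root, cost=8.0)
        assert route_length(route) == 5
        assert route.n_reactions == 7  # 1 + 2 + 4

    def test_single_purchasable_target_has_length_zero(self):
        route = Route(root=RouteNode(molecule=Molecule.token("T")), cost=0.0)
        assert route_length(route) == 0

    @pytest.mark.parametrize("sm_present,all_purchasable,expected", [
        (True, True, True),
        (False, True, False),
        (True, False, False),
        (False, False, False),
    ])
    def test_constrained_solve_truth_table(self, sm_present, all_purchasable,
                                           expected):
        sm = Molecule.token("SM")
        other_leaf = Molecule.token("F")
        leaves = [RouteNode(molecule=other_leaf)]
        if sm_present:
            leaves.append(RouteNode(molecule=sm))
        root = RouteNode(molecule=Molecule.token("T"), children=tuple(leaves))
        route = Route(root=root, cost=1.0)
        blocks = {"tok:F"} if all_purchasable else set()
        config = SearchConfig(expansion_budget=1,
                              building_blocks=frozenset(blocks),
                              enforced_sm=sm)
        assert is_constrained_solved(route, config) is expected


class TestRouteSerialization:
    def test_json_round_trip(self, tmp_path):
        net = generate(depth=3, branching=2, decoy_rate=0.3, seed=2,
                       mode="real")
        result = search(net.target, net.policy(), make_config(net, budget=40))
        assert result.solved
        path = tmp_path / "route.json"
        save_route(result.route, path)
        loaded = load_route(path)
        assert loaded.to_json_dict() == result.route.to_json_dict()
        assert loaded.reaction_smiles() == result.route.reaction_smiles()
        assert all(">>" in line for line in loaded.reaction_smiles())
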