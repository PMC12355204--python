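"""Benchmark metrics and cost-function diagnostics."""

import json

import numpy as np
import pytest

from tangoplan import (
    BenchmarkProblem,
    CostWeights,
    InsufficientDataError,
    PathError,
    canonicalize,
    diagnostics,
    generate,
    route_node_costs,
    run_benchmark,
    tango_pairwise_cost,
)


def problems_from_networks(n, depth=4, branching=3, decoy_rate=0.4,
                           mode="real", seed0=0):
    probs = []
    for i in range(n):
        net = generate(depth=depth, branching=branching,
                       decoy_rate=decoy_rate, seed=seed0 + i, mode=mode)
        probs.append(BenchmarkProblem(
            name=f"net-{seed0 + i}", target=net.target, sm=net.enforced_sm,
            policy=net.policy(), building_blocks=net.building_blocks))
    return probs


@pytest.fixture(scope="module")
def small_report():
    probs = problems_from_networks(10)
    settings = {"tango": CostWeights(k=25.0), "unguided": CostWeights(k=0.0)}
    return run_benchmark(probs, budgets=[6, 15, 60], cost_settings=settings)


class TestBenchmark:
    def test_all_planted_problems_solve_at_full_budget(self, small_report):
        assert small_report.solve_rate("tango", 60) == pytest.approx(100.0)

    def test_solve_rate_monotone_in_budget(self, small_report):
        for setting in ("tango", "unguided"):
            rates = [small_report.solve_rate(setting, b)
                     for b in small_report.budgets]
            assert rates == sorted(rates)

    def test_guided_uses_fewer_expansions(self, small_report):
        assert small_report.n_bar("tango") < small_report.n_bar("unguided")

    def test_checkpoint_matches_independent_capped_run(self):
        """Solve state recovered from solve_iteration at budget b must
        agree with an actual search capped at b."""
        probs = problems_from_networks(5, seed0=20)
        settings = {"tango": CostWeights(k=25.0)}
        b = 6
        report = run_benchmark(probs, budgets=[b, 40], cost_settings=settings)
        capped = run_benchmark(probs, budgets=[b], cost_settings=settings)
        for rec_full, rec_capped in zip(report.records["tango"],
                                        capped.records["tango"]):
            full_solved_at_b = (rec_full.solved
                                and rec_full.solve_iteration <= b)
            assert full_solved_at_b == rec_capped.solved

    def test_route_length_on_common_subset(self, small_report):
        common = small_report.common_solved()
        assert set(common) <= {r.name for r in small_report.records["tango"]}
        if common:
            assert small_report.mean_route_length("tango") > 0

    def test_report_serialization_round_trips(self, small_report, tmp_path):
        csv_path, json_path = tmp_path / "r.csv", tmp_path / "r.json"
        small_report.save(csv_path=csv_path, json_path=json_path)
        agg = json.loads(json_path.read_text())
        assert agg["settings"]["tango"]["solve_rate"]["60"] == \
            pytest.approx(small_report.solve_rate("tango", 60))
        df = small_report.to_dataframe()
        assert len(df) == 2 * 10

    def test_empty_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            run_benchmark([], [10], {"x": CostWeights()})


class TestRouteNodeCosts:
    def test_distances_walk_root_to_sm(self):
        net = generate(depth=4, branching=1, decoy_rate=0.0, seed=0,
                       mode="real")
        cost = tango_pairwise_cost(CostWeights(k=25.0))
        recs = route_node_costs(net.planted_route, net.enforced_sm, cost)
        assert [d for d, _ in recs] == [4, 3, 2, 1, 0]

    def test_zero_cost_at_distance_zero(self):
        net = generate(depth=3, branching=1, decoy_rate=0.0, seed=1,
                       mode="real")
        cost = tango_pairwise_cost(CostWeights(k=25.0, c=0.3))
        recs = route_node_costs(net.planted_route, net.enforced_sm, cost)
        assert recs[-1][0] == 0
        assert recs[-1][1] == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [0.0, 0.3])
    def test_tango_cost_non_increasing_toward_sm(self, c):
        for seed in range(5):
            net = generate(depth=5, branching=2, decoy_rate=0.3, seed=seed,
                           mode="real")
            cost = tango_pairwise_cost(CostWeights(k=25.0, c=c))
            costs = [v for _, v in route_node_costs(
                net.planted_route, net.enforced_sm, cost)]
            assert all(costs[i] >= costs[i + 1] - 1e-9
                       for i in range(len(costs) - 1))

    def test_missing_sm_raises(self):
        net = generate(depth=3, branching=1, decoy_rate=0.0, seed=2,
                       mode="real")
        with pytest.raises(PathError):
            route_node_costs(net.planted_route, canonicalize("CCCCCCCCCC"),
                             lambda m, s: 0.0)


class TestDiagnostics:
    def test_perfectly_monotone_costs(self):
        records = [(d, float(d)) for d in (5, 4, 3, 2, 1)] * 3
        rep = diagnostics(records)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)

    def test_constant_within_group_costs_have_zero_cv(self):
        records = [(1, 2.0)] * 10 + [(2, 5.0)] * 10
        rep = diagnostics(records)
        assert rep.mean_cv == pytest.approx(0.0)
        assert (rep.group_stats["std"] == 0).all()

    def test_separation_ratio_recovers_closed_form(self):
        """Two adjacent Normal(1, .1) / Normal(2, .1) groups: the ratio
        (s1+s2)/|m1-m2| has closed form 0.2."""
        rng = np.random.default_rng(12345)
        records = [(1, x) for x in rng.normal(1.0, 0.1, 500)]
        records += [(2, x) for x in rng.normal(2.0, 0.1, 500)]
        rep = diagnostics(records)
        assert rep.mean_overlap == pytest.approx(0.2, abs=0.02)

    def test_histogram_overlap_alternative_bounded(self):
        rng = np.random.default_rng(7)
        records = [(1, x) for x in rng.normal(0.0, 1.0, 300)]
        records += [(2, x) for x in rng.normal(0.5, 1.0, 300)]
        rep = diagnostics(records, overlap_method="histogram")
        assert 0.0 <= rep.mean_overlap <= 1.0
        assert rep.overlap_method == "histogram"

    def test_perfect_oracle_on_planted_routes(self):
        records = []
        for seed in range(5):
            net = generate(depth=4, branching=2, decoy_rate=0.3, seed=seed,
                           mode="abstract")
            oracle = net.oracle_cost()
            records.extend(route_node_costs(
                net.planted_route, net.enforced_sm,
                lambda m, _sm: oracle(m)))
        rep = diagnostics(records)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)
        assert rep.mean_cv == pytest.approx(0.0)

    def test_zero_mean_groups_excluded_from_cv(self):
        records = [(0, 0.0)] * 5 + [(1, 1.0)] * 5 + [(2, 2.0)] * 5
        rep = diagnostics(records)
        assert rep.cv_excluded_groups == 1
        assert rep.mean_cv == pytest.approx(0.0)

    @pytest.mark.parametrize("records", [
        [(1, 2.0)],
        [(1, 2.0), (1, 3.0)],
    ])
    def test_insufficient_data_rejected(self, records):
        with pytest.raises(InsufficientDataError):
            diagnostics(records)
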