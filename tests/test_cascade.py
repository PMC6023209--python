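import numpy as np
import pytest

from concept_cascade import (
    ConceptSystem,
    Graph,
    assign_ltm_attributes,
    generate_small_world,
    run_icm,
    run_ltm,
    run_single_concept,
)
from conftest import make_random_graph


def reachable_from(g: Graph, seeds) -> set:
    seen = set(seeds)
    stack = list(seeds)
    while stack:
        u = stack.pop()
        for v in g.out_neighbors(u):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


class TestIcm:
    def test_zero_probability_spreads_nothing(self):
        g = make_random_graph(30, 0.2, seed=1)
        cs = ConceptSystem(r=1.0, p=0.0)
        res = run_icm(g, cs, [0, 1, 2], rng_seed=0)
        assert res.final_active_count["t"] == 3
        assert res.final_active_sets["t"] == frozenset({0, 1, 2})

    def test_certain_transmission_fills_reachable_set(self):
        g = make_random_graph(40, 0.08, seed=2)
        cs = ConceptSystem(r=1.0, p=1.0)
        res = run_icm(g, cs, [0], rng_seed=0)
        assert res.final_active_sets["t"] == frozenset(reachable_from(g, [0]))

    def test_path_graph_expected_size_closed_form(self):
        # undirected path A-B-C seeded at A: E[final] = 1 + p + p^2
        g = Graph(3)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=1.0, p=0.1)
        n_runs = 20000
        counts = np.array(
            [
                run_icm(g, cs, [0], rng_seed=i).final_active_count["t"]
                for i in range(n_runs)
            ],
            dtype=float,
        )
        expected = 1 + 0.1 + 0.1**2
        se = counts.std(ddof=1) / np.sqrt(n_runs)
        assert abs(counts.mean() - expected) < 3 * se

    def test_total_inhibition_blocks_all_transmission(self):
        g = make_random_graph(30, 0.3, seed=3)
        cs = ConceptSystem(r=0.0, p=0.5)
        res = run_icm(
            g, cs, [0, 1], controllable_seed_selector=range(30), rng_seed=0
        )
        assert res.final_active_count["t"] == 2

    def test_no_edge_concept_pair_sampled_twice(self):
        g = make_random_graph(60, 0.1, seed=4)
        cs = ConceptSystem(r=2.0, p=0.4)
        res = run_icm(
            g, cs, [0, 1, 2], controllable_seed_selector=[5, 6], burn_in=1,
            rng_seed=9, record_attempts=True,
        )
        assert res.attempted is not None  # internal assertion did not fire

    def test_conservation_per_concept(self):
        g = make_random_graph(80, 0.06, seed=5)
        cs = ConceptSystem(r=1.5, p=0.3)
        res = run_icm(
            g, cs, [0, 1, 2, 3], controllable_seed_selector=[10, 11], burn_in=2,
            rng_seed=11,
        )
        for c, n_seeds in (("t", 4), ("s", 2)):
            assert res.final_active_count[c] == sum(
                res.activations_per_step[c]
            ) + n_seeds

    def test_deterministic_given_seed(self):
        g = make_random_graph(50, 0.1, seed=6)
        cs = ConceptSystem(r=2.0, p=0.3)
        a = run_icm(g, cs, [0], controllable_seed_selector=[1], rng_seed=3)
        b = run_icm(g, cs, [0], controllable_seed_selector=[1], rng_seed=3)
        assert a.final_active_sets == b.final_active_sets
        assert a.activations_per_step == b.activations_per_step

    def test_parameter_validation(self):
        g = make_random_graph(10, 0.3, seed=7)
        cs = ConceptSystem()
        with pytest.raises(ValueError):
            run_icm(g, cs, [0], burn_in=-1)
        with pytest.raises(ValueError):
            run_icm(g, cs, [0], burn_in=5, max_steps=2)
        with pytest.raises(ValueError):
            run_icm(g, cs, [])
        with pytest.raises(ValueError):
            run_icm(g, cs, [99])

    def test_max_steps_zero_returns_seeds_only(self):
        g = make_random_graph(20, 0.5, seed=8)
        cs = ConceptSystem(r=1.0, p=1.0)
        res = run_icm(g, cs, [0, 1], max_steps=0, rng_seed=0)
        assert res.final_active_count["t"] == 2
        assert res.steps_run == 0

    def test_mean_spread_monotone_in_r(self):
        # distributional ordering: r=0 < r=1 < r=2 on a fixed graph
        g = generate_small_world(400, 0.25, 1, rng_seed=1)
        rng = np.random.default_rng(0)
        t_seeds = rng.choice(400, 10, replace=False)
        s_seeds = rng.choice(400, 10, replace=False)
        means = {}
        for r in (0.0, 1.0, 2.0):
            cs = ConceptSystem(r=r, p=0.1)
            vals = [
                run_icm(g, cs, t_seeds, s_seeds, rng_seed=i).final_active_count["t"]
                for i in range(250)
            ]
            means[r] = np.mean(vals)
        assert means[0.0] < means[1.0] < means[2.0]


class TestBurnIn:
    def test_selector_sees_burn_in_frontier(self):
        g = make_random_graph(50, 0.15, seed=9)
        cs = ConceptSystem(r=2.0, p=0.5)
        seen = {}

        def spy_selector(graph, state, concept_system, rng):
            seen["frontier"] = set(state.frontier["t"].tolist())
            seen["active"] = set(np.flatnonzero(state.active["t"]).tolist())
            seen["step"] = state.step_index
            return [0]

        run_icm(g, cs, [0, 1], spy_selector, burn_in=2, rng_seed=4)
        assert seen["step"] == 2
        assert seen["frontier"] <= seen["active"]
        assert {0, 1} <= seen["active"]

    def test_zero_burn_in_frontier_is_seed_set(self):
        g = make_random_graph(30, 0.2, seed=10)
        cs = ConceptSystem(r=2.0, p=0.1)
        seen = {}

        def spy_selector(graph, state, concept_system, rng):
            seen["frontier"] = set(state.frontier["t"].tolist())
            return []

        run_icm(g, cs, [3, 4, 5], spy_selector, burn_in=0, rng_seed=4)
        assert seen["frontier"] == {3, 4, 5}


class TestSingleConceptWrapper:
    def test_bitwise_equal_to_empty_controllable_set(self):
        g = make_random_graph(60, 0.1, seed=11)
        cs = ConceptSystem(r=1.0, p=0.2)
        a = run_single_concept(g, cs, [0, 1], rng_seed=7)
        b = run_icm(g, cs, [0, 1], controllable_seed_selector=frozenset(),
                    burn_in=0, rng_seed=7)
        assert a.final_active_sets == b.final_active_sets
        assert a.activations_per_step == b.activations_per_step
        assert a.steps_run == b.steps_run

    def test_new_infections_decline_by_step_four(self):
        # single concept from 250 random seeds: per-step activations rise
        # then decline, with the decline beginning by step 4
        g = generate_small_world(50000, 0.25, 1, rng_seed=1)
        seeds = np.random.default_rng(2).choice(50000, 250, replace=False)
        cs = ConceptSystem(r=1.0, p=0.1)
        res = run_single_concept(g, cs, seeds, rng_seed=3)
        steps = res.activations_per_step["t"]
        peak = int(np.argmax(steps))
        assert peak <= 3
        assert steps[-1] < steps[peak]


class TestLtm:
    def _two_neighbor_graph(self):
        # node 2 has two in-neighbours, each contributing influence 0.5
        g = Graph(3)
        g.add_edge(0, 2)
        g.add_edge(1, 2)
        g.thresholds = {c: np.array([1.0, 1.0, 1.0]) for c in ("t", "s")}
        g.weights = {
            c: {(0, 2): 0.5, (2, 0): 1.0, (1, 2): 0.5, (2, 1): 1.0}
            for c in ("t", "s")
        }
        return g

    def test_activation_at_summed_threshold(self):
        g = self._two_neighbor_graph()
        cs = ConceptSystem(r=1.0, p=0.1, model_tag="LTM")
        res = run_ltm(g, cs, [0, 1], rng_seed=0)
        assert 2 in res.final_active_sets["t"]  # 0.5 + 0.5 >= 1

    def test_single_contribution_below_threshold(self):
        g = self._two_neighbor_graph()
        cs = ConceptSystem(r=1.0, p=0.1, model_tag="LTM")
        res = run_ltm(g, cs, [0], rng_seed=0)
        assert 2 not in res.final_active_sets["t"]

    def test_inhibiting_context_scales_influence(self):
        g = self._two_neighbor_graph()
        cs = ConceptSystem(r=0.5, p=0.1, model_tag="LTM")
        res = run_ltm(g, cs, [0, 1], controllable_seed_selector=[2], rng_seed=0)
        assert 2 not in res.final_active_sets["t"]  # 0.25 + 0.25 < 1

    def test_deterministic_trajectory(self):
        g = generate_small_world(100, 0.25, 1, rng_seed=0)
        assign_ltm_attributes(g, ["t", "s"], 0.5, 0.1, rng_seed=1)
        cs = ConceptSystem(r=2.0, p=0.1, model_tag="LTM")
        a = run_ltm(g, cs, range(10), controllable_seed_selector=[20], rng_seed=5)
        b = run_ltm(g, cs, range(10), controllable_seed_selector=[20], rng_seed=6)
        assert a.final_active_sets == b.final_active_sets
        assert a.activations_per_step == b.activations_per_step

    def test_missing_attributes_rejected(self):
        g = make_random_graph(10, 0.3, seed=12)
        cs = ConceptSystem(model_tag="LTM")
        with pytest.raises(ValueError):
            run_ltm(g, cs, [0])
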