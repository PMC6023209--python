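import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concept_cascade import (
    ConceptSystem,
    Graph,
    build_state,
    contextual_influence,
    get_selector,
    moboo_paths,
    most_influential_paths,
    score_nodes,
    select_degree,
    select_degree_discount,
    select_moboo,
    select_mpg,
    select_random,
    select_single_discount,
)
from concept_cascade._search import (
    IcmInfluenceSearch,
    ReferenceInfluenceSearch,
    theta_cutoff,
)
from concept_cascade.heuristics import _MoBoo, _mpg_greedy, _mpg_select_fast
from _oracles import enumerate_best_paths, naive_degree_discount
from conftest import make_random_graph


def icm_edge_ci(cs, s_active):
    def ci(u, v):
        return contextual_influence(cs.p, u in s_active, v in s_active, cs.r)

    return ci


class TestMostInfluentialPaths:
    def test_chain_examples_with_theta_pruning(self):
        # 0 -> 1 -> 2 -> 3, p = 0.1, theta = 0.001: the 3-hop product equals
        # theta and is therefore omitted
        g = Graph(4, directed=True)
        for u in range(3):
            g.add_edge(u, u + 1)
        cs = ConceptSystem(r=2.0, p=0.1)
        state = build_state(g, cs, [0])
        table = most_influential_paths(g, 0, state, cs, prune=0.001)
        assert table.ir(1) == pytest.approx(0.1)
        assert table.ir(2) == pytest.approx(0.01)
        assert 3 not in table.entries
        assert table.path(2) == (0, 1, 2)

    def test_chain_with_controllable_context(self):
        # s active on node 1 doubles both its incoming and outgoing edges
        g = Graph(3, directed=True)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=2.0, p=0.1)
        state = build_state(g, cs, [0], controllable_active=[1])
        table = most_influential_paths(g, 0, state, cs, prune=0.001)
        assert table.ir(1) == pytest.approx(0.2)
        assert table.ir(2) == pytest.approx(0.04)

    def test_diamond_picks_the_stronger_path(self):
        # edge influences (A->B->D) = (0.5, 0.1), (A->C->D) = (0.3, 0.3):
        # the most influential path to D runs through C with product 0.09
        g = Graph(4, directed=True)
        g.add_edge(0, 1)
        g.add_edge(0, 2)
        g.add_edge(1, 3)
        g.add_edge(2, 3)
        g.thresholds = {c: np.ones(4) for c in ("t", "s")}
        g.weights = {
            c: {(0, 1): 0.5, (0, 2): 0.3, (1, 3): 0.1, (2, 3): 0.3}
            for c in ("t", "s")
        }
        cs = ConceptSystem(r=1.0, model_tag="LTM")
        state = build_state(g, cs, [0])
        table = most_influential_paths(g, 0, state, cs, prune=3)
        assert table.ir(3) == pytest.approx(0.09)
        assert table.path(3) == (0, 2, 3)

    def test_invalid_theta_rejected(self):
        g = make_random_graph(5, 0.5, seed=0)
        cs = ConceptSystem()
        state = build_state(g, cs, [0])
        for theta in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                most_influential_paths(g, 0, state, cs, prune=theta)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_simple_path_enumeration(self, seed):
        # dyadic probabilities make products exact, so the brute-force
        # enumeration, the reference search and the compiled search must
        # agree to the bit
        rng = np.random.default_rng(seed)
        g = make_random_graph(8, 0.35, seed=seed)
        r = [2.0, 0.5, 0.0][seed % 3]
        cs = ConceptSystem(r=r, p=0.25)
        s_active = set(rng.choice(8, 2, replace=False).tolist()) if seed % 2 else set()
        state = build_state(g, cs, [0], controllable_active=s_active)
        cutoff = theta_cutoff(1 / 64)
        oracle = enumerate_best_paths(
            g.out_neighbors, list(g.nodes()), icm_edge_ci(cs, s_active), 0, cutoff
        )
        table = most_influential_paths(g, 0, state, cs, prune=1 / 64)
        assert set(table.entries) == set(oracle)
        for u, (ir, _) in oracle.items():
            assert table.ir(u) == ir
        fast = IcmInfluenceSearch(g, cs.p, cs.r, 1 / 64)
        for v in s_active:
            fast.activate_s(v)
        nodes, prods, _ = fast.reach(0)
        assert dict(zip(nodes.tolist(), prods.tolist())) == {
            u: ir for u, (ir, _) in oracle.items()
        }

    def test_stored_paths_are_simple_and_realise_the_product(self):
        g = make_random_graph(8, 0.4, seed=99)
        cs = ConceptSystem(r=2.0, p=0.25)
        state = build_state(g, cs, [0], controllable_active=[3])
        ci = icm_edge_ci(cs, {3})
        table = most_influential_paths(g, 0, state, cs, prune=1 / 64)
        for u, (ir, path) in table.entries.items():
            assert path[0] == 0 and path[-1] == u
            assert len(set(path)) == len(path)
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= ci(a, b)
            assert prod == ir
            assert ir > theta_cutoff(1 / 64)


class TestScoreNodes:
    def test_empty_spreading_set_scores_zero(self):
        g = make_random_graph(10, 0.3, seed=1)
        cs = ConceptSystem(r=2.0, p=0.1)
        state = build_state(g, cs, [], target_frontier=[])
        scores = score_nodes(g, state, cs)
        assert scores.ap == {} and scores.we == {}

    def test_directed_chain_scores(self):
        # 0 -> 1 -> 2, p=0.1, r=2, theta=0.001; E uses the current context
        g = Graph(3, directed=True)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=2.0, p=0.1)
        state = build_state(g, cs, [0])
        scores = score_nodes(g, state, cs, prune=0.001)
        assert scores.ap_of(1) == pytest.approx(0.1)
        assert scores.e_of(1) == pytest.approx(0.1)
        assert scores.we_of(1) == pytest.approx(0.01)
        assert scores.ap_of(0) == 0.0

    def test_ap_is_additive_over_sources(self):
        # two seeds reach node 3 with IR 0.1 (direct) and 0.01 (two hops)
        g = Graph(4, directed=True)
        g.add_edge(0, 3)
        g.add_edge(1, 2)
        g.add_edge(2, 3)
        cs = ConceptSystem(r=2.0, p=0.1)
        state = build_state(g, cs, [0, 1])
        scores = score_nodes(g, state, cs, prune=0.001)
        assert scores.ap_of(3) == pytest.approx(0.11)

    def test_we_invariant(self):
        g = make_random_graph(20, 0.2, seed=3)
        cs = ConceptSystem(r=2.0, p=0.2)
        state = build_state(g, cs, [0, 1, 2])
        scores = score_nodes(g, state, cs)
        for u in scores.we:
            assert scores.we[u] == pytest.approx(scores.ap[u] * scores.e[u])
            assert scores.ap[u] >= 0 and scores.e[u] >= 0


class TestSelectMpg:
    def test_k_zero_empty(self, star10, icm_boost):
        state = build_state(star10, icm_boost, [1])
        assert select_mpg(star10, state, icm_boost, 0) == []

    def test_star_hub_selected_first(self, star10, icm_boost):
        # hub is the only node combining ap > 0 with large downstream reach
        state = build_state(star10, icm_boost, [1])
        chosen = select_mpg(star10, state, icm_boost, 1)
        assert chosen == [0]

    def test_no_spreading_set_falls_back_to_id_order(self, star10, icm_boost):
        state = build_state(star10, icm_boost, [], target_frontier=[])
        assert select_mpg(star10, state, icm_boost, 3) == [0, 1, 2]

    def test_k_equal_n_returns_every_node(self, triangle_pendant, icm_boost):
        state = build_state(triangle_pendant, icm_boost, [0])
        chosen = select_mpg(triangle_pendant, state, icm_boost, 4)
        assert sorted(chosen) == [0, 1, 2, 3]

    def test_k_exceeding_n_rejected(self, clique5, icm_boost):
        state = build_state(clique5, icm_boost, [0])
        with pytest.raises(ValueError):
            select_mpg(clique5, state, icm_boost, 6)

    @pytest.mark.parametrize("trial", range(18))
    def test_fast_and_reference_paths_agree(self, trial):
        rng = np.random.default_rng(trial)
        g = make_random_graph(12, 0.25, seed=trial)
        r = [2.0, 0.0, 0.5][trial % 3]
        cs = ConceptSystem(r=r, p=0.25)
        seeds = sorted(rng.choice(12, 3, replace=False).tolist())
        theta = 1 / 64
        fast = IcmInfluenceSearch(g, cs.p, cs.r, theta)
        ref = ReferenceInfluenceSearch(g, cs, theta)
        a = _mpg_select_fast(fast, 12, seeds, 6)
        b = _mpg_greedy(ref, 12, seeds, 6, theta_cutoff(theta))
        assert a == b

    def test_deterministic(self):
        g = make_random_graph(30, 0.15, seed=5)
        cs = ConceptSystem(r=2.0, p=0.2)
        state = build_state(g, cs, [0, 1])
        assert select_mpg(g, state, cs, 5) == select_mpg(g, state, cs, 5)


class TestDegreeBasedSelectors:
    def test_degree_discount_matches_naive_reevaluation(self):
        for seed in range(6):
            g = make_random_graph(25, 0.2, seed=seed)
            adj = [sorted(g.out_neighbors(u)) for u in g.nodes()]
            for p in (0.0, 0.1, 0.5):
                assert select_degree_discount(g, 8, p) == naive_degree_discount(
                    adj, 8, p
                )

    def test_degree_discount_formula_spot_value(self):
        # d=10, t=2, p=0.1 -> 10 - 4 - 8*0.2 = 4.4 steers the selection
        d, t, p = 10, 2, 0.1
        assert d - 2 * t - (d - t) * t * p == pytest.approx(4.4)
        # and with t=0 the score reduces to the plain degree
        assert d - 2 * 0 - (d - 0) * 0 * p == d

    def test_triangle_pendant_selection_order(self, triangle_pendant):
        adj = [sorted(triangle_pendant.out_neighbors(u)) for u in range(4)]
        expected = naive_degree_discount(adj, 4, 0.1)
        assert select_degree_discount(triangle_pendant, 4, 0.1) == expected
        assert expected[0] == 0  # the degree-3 node leads

    def test_degree_discount_p_zero_coincides_with_d_minus_2t(self):
        for seed in range(4):
            g = make_random_graph(20, 0.25, seed=seed + 50)
            adj = [sorted(g.out_neighbors(u)) for u in g.nodes()]
            assert select_degree_discount(g, 10, 0.0) == naive_degree_discount(
                adj, 10, 0.0
            )

    def test_degree_on_star(self, star10):
        assert select_degree(star10, 1) == [0]

    def test_single_discount_clique_selects_all(self, clique5):
        assert sorted(select_single_discount(clique5, 5)) == [0, 1, 2, 3, 4]
        # tie rule: lowest id first throughout
        assert select_single_discount(clique5, 5) == [0, 1, 2, 3, 4]

    def test_random_reproducible_and_distinct(self, clique5):
        a = select_random(clique5, 3, rng_seed=11)
        b = select_random(clique5, 3, rng_seed=11)
        assert a == b
        assert len(set(a)) == 3

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 1000), k=st.integers(0, 15))
    def test_all_selectors_return_k_distinct_nodes(self, seed, k):
        g = make_random_graph(15, 0.25, seed=seed)
        cs = ConceptSystem(r=2.0, p=0.25)
        state = build_state(g, cs, [0, 1])
        rng = np.random.default_rng(0)
        for name in ("random", "degree", "single_discount", "degree_discount",
                     "moboo", "mpg"):
            sel = get_selector(name, k)(g, state, cs, rng)
            assert len(sel) == k
            assert len(set(sel)) == k
            assert all(0 <= u < 15 for u in sel)


class TestMoBoo:
    def test_two_disjoint_half_paths_combine(self):
        # two internally disjoint paths with probability 0.5 each:
        # ap = 1 - (1 - 0.5)**2 = 0.75
        g = Graph(3)
        g.add_edge(0, 2)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=2.0, p=0.5)
        state = build_state(g, cs, [0, 1])
        paths = moboo_paths(g, state, cs, lam=2, prune=0.01)
        assert paths.ap[2] == pytest.approx(0.75)
        assert len(paths.paths[2]) == 2

    def test_single_path_probability(self):
        g = Graph(2, directed=True)
        g.add_edge(0, 1)
        g.thresholds = {c: np.ones(2) for c in ("t", "s")}
        g.weights = {c: {(0, 1): 0.3} for c in ("t", "s")}
        cs = ConceptSystem(r=2.0, model_tag="LTM")
        state = build_state(g, cs, [0])
        paths = moboo_paths(g, state, cs, lam=2, prune=3)
        assert paths.ap[1] == pytest.approx(0.3)

    def test_neutral_relationship_rejected(self, clique5):
        cs = ConceptSystem(r=1.0, p=0.1)
        state = build_state(clique5, cs, [0])
        with pytest.raises(ValueError, match="neutral"):
            select_moboo(clique5, state, cs, 2)

    def test_gain_sums_descendant_ap_with_uniform_probabilities(self):
        # chain 0 - 1 - 2 with p = 0.5, r = 2: g(1) = (r-1) * ap(2) = 0.25;
        # the terminal node 2 relays nothing, so g(2) = 0
        g = Graph(3)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=2.0, p=0.5)
        state = build_state(g, cs, [0])
        mb = _MoBoo(g, state, cs, lam=2, prune=0.01)
        assert mb.ap[1] == pytest.approx(0.5)
        assert mb.ap[2] == pytest.approx(0.25)
        assert mb.gain[1] == pytest.approx(0.25)
        assert mb.gain.get(2, 0.0) == 0.0
        # the relay node is selected first
        assert select_moboo(g, state, cs, 1, prune=0.01) == [1]

    def test_spreading_roots_are_not_candidates(self):
        g = Graph(3)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        cs = ConceptSystem(r=2.0, p=0.5)
        state = build_state(g, cs, [0])
        chosen = select_moboo(g, state, cs, 2, prune=0.01)
        assert chosen[0] != 0  # node 0 is the spreading root

    def test_deterministic(self):
        g = make_random_graph(25, 0.2, seed=13)
        cs = ConceptSystem(r=2.0, p=0.3)
        state = build_state(g, cs, [0, 1, 2])
        assert select_moboo(g, state, cs, 5) == select_moboo(g, state, cs, 5)
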