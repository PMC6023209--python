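"""Seed-selection heuristics for the controllable concept.

Six selectors are provided: uniform random, highest degree, single
discount, degree discount, MoBoo (gain over node-disjoint most-probable
activation paths) and MPG (maximum potential gain).  MPG greedily selects
the node with the highest weighted expected gain

    WE(u) = ap(u) * E(u),

where ``ap(u)`` sums the influence received from every currently spreading
target-concept node along most-influential paths, and ``E(u)`` sums the
influence ``u`` exerts on its own pruned neighbourhood in the current
context.  After each selection the chosen node carries the controllable
concept, which rescales nearby edge influences, and the scores of affected
nodes are recomputed.

All deterministic selectors break ties by lowest node id.
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

import numpy as np

from ._search import (
    IcmInfluenceSearch,
    ReferenceInfluenceSearch,
    theta_cutoff,
)
from .cascade import NetworkState
from .graphs import Graph
from .interaction import ICM, LTM, ConceptSystem

__all__ = [
    "InfluenceTable",
    "NodeScores",
    "MoBooPaths",
    "build_state",
    "most_influential_paths",
    "score_nodes",
    "select_mpg",
    "select_degree_discount",
    "select_single_discount",
    "select_degree",
    "select_random",
    "select_moboo",
    "moboo_paths",
    "get_selector",
    "HEURISTIC_NAMES",
    "DEFAULT_THETA",
    "DEFAULT_HOP_LIMIT",
]

#: pruning threshold for ICM path exploration (influence values <= theta
#: are treated as zero) and hop limit for LTM exploration (paths of node
#: length <= 4, i.e. the 3-hop neighbourhood).
DEFAULT_THETA = 0.001
DEFAULT_HOP_LIMIT = 3

_AP_EPS = 1e-15  # float dust cut for incrementally maintained ap sums


# ---------------------------------------------------------------------------
# Score containers
# ---------------------------------------------------------------------------


@dataclass
class InfluenceTable:
    """Influence received from ``source`` within the pruned horizon.

    ``entries[u] = (ir, path)`` where ``ir`` is the product of contextual
    influences along ``path``, the most influential simple path from
    ``source`` to ``u``; only values strictly above the pruning threshold
    are stored.
    """

    source: int
    entries: Dict[int, Tuple[float, Tuple[int, ...]]]

    def ir(self, node: int) -> float:
        e = self.entries.get(node)
        return e[0] if e else 0.0

    def path(self, node: int) -> Optional[Tuple[int, ...]]:
        e = self.entries.get(node)
        return e[1] if e else None


@dataclass
class NodeScores:
    """ap, E and WE = ap * E per node; absent nodes score zero."""

    ap: Dict[int, float] = field(default_factory=dict)
    e: Dict[int, float] = field(default_factory=dict)
    we: Dict[int, float] = field(default_factory=dict)

    def ap_of(self, u: int) -> float:
        return self.ap.get(u, 0.0)

    def e_of(self, u: int) -> float:
        return self.e.get(u, 0.0)

    def we_of(self, u: int) -> float:
        return self.we.get(u, 0.0)


@dataclass
class MoBooPaths:
    """Up to ``lam`` internally node-disjoint activation paths per node.

    ``paths[v]`` lists (probability, path) pairs ordered by decreasing
    probability; the paths share only the end node ``v`` (and possibly the
    start node).  ``ap[v] = 1 - prod(1 - P_i)``.
    """

    lam: int
    paths: Dict[int, List[Tuple[float, Tuple[int, ...]]]]
    ap: Dict[int, float]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def build_state(
    g: Graph,
    cs: ConceptSystem,
    target_active: Iterable[int],
    controllable_active: Iterable[int] = (),
    target_frontier: Optional[Iterable[int]] = None,
) -> NetworkState:
    """Construct a :class:`NetworkState` snapshot for selector calls.

    ``target_frontier`` defaults to the full ``target_active`` set (the
    start-of-cascade convention where S_t is the initial seed set).
    """
    n = g.n_nodes
    t, s = cs.target_id, cs.controllable_id
    active = {t: np.zeros(n, dtype=bool), s: np.zeros(n, dtype=bool)}
    tlist = sorted(set(int(x) for x in target_active))
    slist = sorted(set(int(x) for x in controllable_active))
    active[t][tlist] = True
    active[s][slist] = True
    frontier_t = (
        np.asarray(sorted(set(int(x) for x in target_frontier)), dtype=np.int64)
        if target_frontier is not None
        else np.asarray(tlist, dtype=np.int64)
    )
    frontier = {t: frontier_t, s: np.asarray(slist, dtype=np.int64)}
    return NetworkState(active=active, frontier=frontier, step_index=0)


def _default_prune(cs: ConceptSystem) -> Union[float, int]:
    return DEFAULT_THETA if cs.model_tag == ICM else DEFAULT_HOP_LIMIT


def _spreading_set(state: NetworkState, cs: ConceptSystem) -> List[int]:
    return sorted(int(x) for x in state.spreading_nodes(cs.target_id, cs.model_tag))


def _make_searcher(g: Graph, state: NetworkState, cs: ConceptSystem, prune):
    """Compiled searcher for undirected ICM graphs, reference otherwise."""
    if cs.model_tag == ICM and not g.directed:
        searcher = IcmInfluenceSearch(g, cs.p, cs.r, float(prune))
        for u in np.flatnonzero(state.active[cs.controllable_id]):
            searcher.activate_s(int(u))
        return searcher
    searcher = ReferenceInfluenceSearch(g, cs, prune)
    searcher.seed_context(np.flatnonzero(state.active[cs.controllable_id]).tolist())
    return searcher


def _check_k(k: int, n: int) -> None:
    if k < 0:
        raise ValueError("seed count k must be nonnegative")
    if k > n:
        raise ValueError(f"cannot select {k} seeds from {n} nodes")


# ---------------------------------------------------------------------------
# Path influence scoring (MPG machinery)
# ---------------------------------------------------------------------------


def most_influential_paths(
    g: Graph,
    source: int,
    state: NetworkState,
    cs: ConceptSystem,
    prune: Union[float, int, None] = None,
) -> InfluenceTable:
    """Most influential path and received influence from ``source``.

    Best-first max-product search over out-edges whose values are the
    contextual influences of the target concept in the state's current
    controllable-concept context.  For the ICM, exploration stops once the
    running product is no longer strictly above ``prune`` (theta); for the
    LTM, paths are limited to the 3-hop neighbourhood (node length 4).
    """
    if prune is None:
        prune = _default_prune(cs)
    if cs.model_tag == ICM and not 0.0 < float(prune) < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    searcher = ReferenceInfluenceSearch(g, cs, prune)
    searcher.seed_context(np.flatnonzero(state.active[cs.controllable_id]).tolist())
    nodes, prods, paths = searcher.reach(int(source), with_paths=True)
    entries = {
        int(u): (float(p), tuple(paths[int(u)])) for u, p in zip(nodes, prods)
    }
    return InfluenceTable(source=int(source), entries=entries)


def score_nodes(
    g: Graph,
    state: NetworkState,
    cs: ConceptSystem,
    prune: Union[float, int, None] = None,
) -> NodeScores:
    """ap, E and WE scores in the state's current context.

    ``ap(u)`` sums IR(v, u) over the spreading set S_t; ``E(u)`` is computed
    only for nodes with some chance of activating the target concept
    (ap > 0) as the sum of IR(u, w) over u's own pruned horizon.
    """
    if prune is None:
        prune = _default_prune(cs)
    searcher = _make_searcher(g, state, cs, prune)
    sources = _spreading_set(state, cs)
    scores = NodeScores()
    for src in sources:
        nodes, prods, _ = searcher.reach(src)
        for u, ir in zip(nodes.tolist(), prods.tolist()):
            scores.ap[u] = scores.ap.get(u, 0.0) + ir
    scored = sorted(u for u, a in scores.ap.items() if a > 0)
    evals = searcher.e_values(scored)
    for u, ev in zip(scored, evals):
        scores.e[u] = float(ev)
        scores.we[u] = scores.ap[u] * float(ev)
    return scores


def select_mpg(
    g: Graph,
    state: NetworkState,
    cs: ConceptSystem,
    k: int,
    prune: Union[float, int, None] = None,
) -> List[int]:
    """Greedy maximum-potential-gain seed selection.

    Repeatedly selects the node with the highest WE = ap * E (ties to the
    lowest id) and marks it as carrying the controllable concept.  Scores
    are maintained on the pruned most-influential-path arborescences built
    when scoring is initialised: after each selection, stored path products
    are re-evaluated under the updated edge context — E(u) for nodes whose
    pruned influence neighbourhood contains the selected node, ap(u) for
    nodes reached through it from the spreading set — with the pruning
    filter reapplied.  Paths are not re-routed (fixed-arborescence updates,
    as in PMIA-style influence estimation).  When every remaining WE is
    zero, selection falls back to lowest node id.
    """
    _check_k(k, g.n_nodes)
    if prune is None:
        prune = _default_prune(cs)
    sources = _spreading_set(state, cs)
    if cs.model_tag == ICM and not g.directed:
        searcher = _make_searcher(g, state, cs, prune)
        return _mpg_select_fast(searcher, g.n_nodes, sources, k)
    searcher = _make_searcher(g, state, cs, prune)
    cutoff = theta_cutoff(float(prune)) if cs.model_tag == ICM else 0.0
    return _mpg_greedy(searcher, g.n_nodes, sources, k, cutoff)


def _mpg_select_fast(
    searcher: IcmInfluenceSearch, n: int, sources: List[int], k: int
) -> List[int]:
    """Array-based MPG greedy loop over compiled frozen arborescences."""
    src_arr = np.asarray(sources, dtype=np.int32)
    ap_forest = searcher.build_forest(src_arr)
    ap_arr = ap_forest.received_sums()
    scored = np.flatnonzero(ap_arr > 0).astype(np.int32)
    e_forest = searcher.build_forest(scored)

    selected: List[int] = []
    sel_mask = np.zeros(n, dtype=bool)
    fallback = 0
    for _ in range(k):
        v = -1
        if scored.size:
            we = ap_arr[scored] * e_forest.evals
            we[sel_mask[scored]] = -1.0
            i = int(np.argmax(we))
            if we[i] > 0.0:
                v = int(scored[i])
        if v < 0:  # every remaining WE is zero: lowest unselected id
            while sel_mask[fallback]:
                fallback += 1
            v = fallback
        selected.append(v)
        sel_mask[v] = True
        if len(selected) == k:
            break
        # the selected node now carries the controllable concept
        searcher.activate_s(v)
        e_forest.refresh(e_forest.trees_containing(v))
        ap_forest.refresh(ap_forest.trees_containing(v), ap_arr)
    return selected


def _mpg_greedy(
    searcher, n: int, sources: List[int], k: int, cutoff: float
) -> List[int]:
    """Reference MPG greedy loop (pure Python, model-agnostic).

    Semantically identical to the compiled path: frozen arborescences with
    stored-path product re-evaluation after each selection.
    """

    def path_prod(path: Tuple[int, ...]) -> float:
        pr = 1.0
        for a, b in zip(path, path[1:]):
            pr *= searcher.edge_ci(a, b)
        return pr

    def filt(pr: float) -> float:
        return pr if pr > cutoff else 0.0

    def build_tree(root: int):
        """Stored arborescence {node: [path, prod]} with a node -> entries
        index (every node of a stored path, root included, maps to the
        entries whose product it can affect)."""
        nodes, prods, paths = searcher.reach(root, with_paths=True)
        tree = {int(u): [paths[int(u)], float(p)] for u, p in zip(nodes, prods)}
        through: Dict[int, List[int]] = defaultdict(list)
        for u, (path, _) in tree.items():
            for x in path:
                through[x].append(u)
        return tree, through

    ap_trees: Dict[int, Tuple[Dict[int, List], Dict[int, List[int]]]] = {}
    ap: Dict[int, float] = defaultdict(float)
    for src in sources:
        ap_trees[src] = build_tree(src)
        for u, (_, pr) in ap_trees[src][0].items():
            ap[u] += filt(pr)

    scored = sorted(u for u, a in ap.items() if a > 0)
    e_trees: Dict[int, Tuple[Dict[int, List], Dict[int, List[int]]]] = {}
    e_val: Dict[int, float] = {}
    for u in scored:
        e_trees[u] = build_tree(u)
        e_val[u] = sum(filt(pr) for _, pr in e_trees[u][0].values())

    def refresh(tree: Dict[int, List], through_v: List[int]) -> float:
        """Re-evaluate the entries whose stored path contains the newly
        selected node; returns the filtered-sum delta."""
        delta = 0.0
        for w in through_v:
            entry = tree[w]
            new = path_prod(entry[0])
            delta += filt(new) - filt(entry[1])
            entry[1] = new
        return delta

    selected: List[int] = []
    selected_set: Set[int] = set()
    fallback = 0
    while len(selected) < k:
        v: Optional[int] = None
        best_we = 0.0
        for u in scored:
            if u in selected_set:
                continue
            we = ap[u] * e_val[u] if ap[u] > 0 else 0.0
            if we > best_we:
                best_we = we
                v = u
        if v is None:  # every remaining WE is zero: lowest unselected id
            while fallback in selected_set:
                fallback += 1
            v = fallback
        selected.append(v)
        selected_set.add(v)
        if len(selected) == k:
            break
        # the selected node now carries the controllable concept
        searcher.activate_s(v)
        for u in scored:
            tree, through = e_trees[u]
            if v in through:
                e_val[u] += refresh(tree, through[v])
        for src, (tree, through) in ap_trees.items():
            if v not in through:
                continue
            for w in through[v]:
                entry = tree[w]
                new = path_prod(entry[0])
                delta = filt(new) - filt(entry[1])
                if delta != 0.0:
                    ap[w] += delta
                entry[1] = new
        for u in scored:
            if abs(ap[u]) < _AP_EPS:
                ap[u] = 0.0
    return selected


# ---------------------------------------------------------------------------
# Degree-based selectors
# ---------------------------------------------------------------------------


def select_degree(g: Graph, k: int) -> List[int]:
    """Top-k nodes by degree, ties to the lowest id."""
    _check_k(k, g.n_nodes)
    order = sorted(range(g.n_nodes), key=lambda u: (-g.degree(u), u))
    return order[:k]


def select_single_discount(g: Graph, k: int) -> List[int]:
    """Greedy highest degree discounted by already-selected neighbours."""
    _check_k(k, g.n_nodes)
    deg = g.degrees()
    score = deg.astype(np.float64)
    heap = [(-score[u], u) for u in range(g.n_nodes)]
    heapq.heapify(heap)
    selected: List[int] = []
    chosen = np.zeros(g.n_nodes, dtype=bool)
    while len(selected) < k:
        negs, u = heapq.heappop(heap)
        if chosen[u] or -negs != score[u]:
            continue
        chosen[u] = True
        selected.append(u)
        for v in g.out_neighbors(u):
            if not chosen[v]:
                score[v] -= 1.0
                heapq.heappush(heap, (-score[v], v))
    return selected


def select_degree_discount(g: Graph, k: int, p: float) -> List[int]:
    """Degree discount: score d_v - 2 t_v - (d_v - t_v) * t_v * p.

    ``t_v`` counts a node's already-selected neighbours; ``p`` is the ICM
    transmission probability.  With ``t_v = 0`` the score reduces to the
    plain degree.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    _check_k(k, g.n_nodes)
    deg = g.degrees().astype(np.float64)
    t = np.zeros(g.n_nodes, dtype=np.float64)
    score = deg.copy()
    heap = [(-score[u], u) for u in range(g.n_nodes)]
    heapq.heapify(heap)
    selected: List[int] = []
    chosen = np.zeros(g.n_nodes, dtype=bool)
    while len(selected) < k:
        negs, u = heapq.heappop(heap)
        if chosen[u] or -negs != score[u]:
            continue
        chosen[u] = True
        selected.append(u)
        for v in g.out_neighbors(u):
            if not chosen[v]:
                t[v] += 1.0
                score[v] = deg[v] - 2.0 * t[v] - (deg[v] - t[v]) * t[v] * p
                heapq.heappush(heap, (-score[v], v))
    return selected


def select_random(g: Graph, k: int, rng_seed: Union[int, np.random.Generator] = 0) -> List[int]:
    """k distinct nodes drawn uniformly without replacement."""
    _check_k(k, g.n_nodes)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return [int(x) for x in rng.choice(g.n_nodes, size=k, replace=False)]


# ---------------------------------------------------------------------------
# MoBoo
# ---------------------------------------------------------------------------


def _internally_disjoint(p1: Tuple[int, ...], p2: Tuple[int, ...], end: int) -> bool:
    shared = set(p1) & set(p2)
    shared.discard(end)
    if p1[0] == p2[0]:
        shared.discard(p1[0])
    return not shared


class _MoBoo:
    """Shared machinery for MoBoo path construction and greedy selection."""

    def __init__(self, g: Graph, state: NetworkState, cs: ConceptSystem,
                 lam: int, prune):
        if lam < 1:
            raise ValueError("lambda must be at least 1")
        self.g = g
        self.cs = cs
        self.lam = lam
        self.r = cs.r
        # trees are grown under base probabilities (no boost context): the
        # boost model below is applied when stored paths are re-evaluated
        if cs.model_tag == ICM and not g.directed:
            self.searcher = IcmInfluenceSearch(g, cs.p, cs.r, float(prune))
        else:
            self.searcher = ReferenceInfluenceSearch(g, cs, prune)
        self.sources = _spreading_set(state, cs)
        # MoBoo's internal spread model: a selected (boosting) node improves
        # its own outgoing edges to p' = min(1, p * r); unlike the cascade's
        # two-endpoint contextual rule, incoming edges are not scaled
        self.boosted: Set[int] = set(
            int(u) for u in np.flatnonzero(state.active[cs.controllable_id])
        )
        # frozen most-probable-path trees: src -> {node: [path, prob]};
        # path structure is fixed, probabilities are re-evaluated under the
        # current boost context after each selection.
        self.trees: Dict[int, Dict[int, List]] = {}
        self.rev: Dict[int, Set[int]] = defaultdict(set)
        self.paths_of: Dict[int, List[Tuple[float, Tuple[int, ...]]]] = {}
        self.ap: Dict[int, float] = {}
        self.node_owner: Dict[int, Set[int]] = defaultdict(set)
        self.contrib_of: Dict[int, List[Tuple[int, float]]] = {}
        self.gain: Dict[int, float] = defaultdict(float)
        self.dirty: Set[int] = set()
        for src in self.sources:
            nodes, prods, paths = self.searcher.reach(src, with_paths=True)
            self.trees[src] = {
                int(u): [paths[int(u)], float(p)] for u, p in zip(nodes, prods)
            }
            for u in self.trees[src]:
                self.rev[u].add(src)
        if self.boosted:
            for src in self.trees:
                self._refresh_tree(src)
        for w in sorted(self.rev):
            self._rebuild_owner(w)

    def _base_prob(self, a: int, b: int) -> float:
        from .interaction import influence_strength_ltm

        if self.cs.model_tag == ICM:
            return self.cs.p
        return influence_strength_ltm(
            self.g.ltm_weight(a, b, self.cs.target_id),
            self.g.ltm_threshold(b, self.cs.target_id),
        )

    def _edge_prob(self, a: int, b: int) -> float:
        base = self._base_prob(a, b)
        if a in self.boosted:
            return min(1.0, base * self.r)
        return base

    def _path_prod(self, path: Tuple[int, ...]) -> float:
        pr = 1.0
        for a, b in zip(path, path[1:]):
            pr *= self._edge_prob(a, b)
        return pr

    def _refresh_tree(self, src: int) -> None:
        for entry in self.trees[src].values():
            entry[1] = self._path_prod(entry[0])

    def _rebuild_owner(self, w: int) -> None:
        # drop previous paths/contributions of w
        for _, path in self.paths_of.get(w, ()):  # pragma: no branch
            for node in path:
                self.node_owner[node].discard(w)
        for a, val in self.contrib_of.get(w, ()):
            self.gain[a] -= val
            self.dirty.add(a)
        chosen: List[Tuple[float, Tuple[int, ...]]] = []
        cands = sorted(
            (-self.trees[src][w][1], src) for src in self.rev.get(w, ())
        )
        for negir, src in cands:
            if negir >= 0.0:  # zero-probability candidates cannot activate w
                continue
            path = self.trees[src][w][0]
            if all(_internally_disjoint(path, q, w) for _, q in chosen):
                chosen.append((-negir, path))
                if len(chosen) == self.lam:
                    break
        if not chosen:
            self.paths_of.pop(w, None)
            self.contrib_of.pop(w, None)
            self.ap.pop(w, None)
            return
        apw = 1.0
        for prob, _ in chosen:
            apw *= 1.0 - prob
        apw = 1.0 - apw
        self.ap[w] = apw
        contribs: List[Tuple[int, float]] = []
        for _, path in chosen:
            for a, b in zip(path, path[1:]):
                ci_ab = self._edge_prob(a, b)
                if ci_ab <= 0.0:
                    continue
                factor = min(1.0, ci_ab * self.r) / ci_ab - 1.0
                val = factor * apw
                if val != 0.0:
                    self.gain[a] += val
                    contribs.append((a, val))
                self.dirty.add(a)
            for node in path:
                self.node_owner[node].add(w)
        self.paths_of[w] = chosen
        self.contrib_of[w] = contribs

    def snapshot(self) -> MoBooPaths:
        return MoBooPaths(
            lam=self.lam,
            paths={w: list(ps) for w, ps in self.paths_of.items()},
            ap=dict(self.ap),
        )

    def select(self, k: int) -> List[int]:
        n = self.g.n_nodes
        _check_k(k, n)
        maximise = self.r > 1.0
        key = (lambda u: (-self.gain[u], u)) if maximise else (
            lambda u: (self.gain[u], u)
        )
        # candidates are the nodes MoBoo built activation paths for; the
        # already-spreading roots have no activation paths and no gain
        candidates = set(self.ap)
        gval = {u: self.gain[u] for u in candidates}
        heap = [key(u) for u in candidates]
        heapq.heapify(heap)
        selected: List[int] = []
        selected_set: Set[int] = set()
        fallback = 0
        while len(selected) < k:
            v: Optional[int] = None
            while heap:
                head, u = heap[0]
                cur = gval.get(u, 0.0)
                cur_head = -cur if maximise else cur
                if u in selected_set or head != cur_head:
                    heapq.heappop(heap)
                    continue
                if (maximise and cur <= 0.0) or (not maximise and cur >= 0.0):
                    break
                heapq.heappop(heap)
                v = u
                break
            if v is None:  # no strictly useful gain left: lowest unselected id
                while fallback in selected_set:
                    fallback += 1
                v = fallback
            selected.append(v)
            selected_set.add(v)
            if len(selected) == k:
                break
            # update the required paths: stored paths touching the selected
            # node get their probabilities re-evaluated (structure frozen)
            affected_src = [
                src for src in self.trees if v in self.trees[src] or src == v
            ]
            self.boosted.add(v)
            owners: Set[int] = set()
            for src in affected_src:
                self._refresh_tree(src)
                owners |= set(self.trees[src])
            for w in sorted(owners):
                self._rebuild_owner(w)
            for u in self.dirty:
                if u in selected_set or u not in candidates:
                    continue
                gval[u] = self.gain[u]
                heapq.heappush(heap, key(u))
            self.dirty.clear()
        return selected


def moboo_paths(
    g: Graph,
    state: NetworkState,
    cs: ConceptSystem,
    lam: int = 2,
    prune: Union[float, int, None] = None,
) -> MoBooPaths:
    """The node-disjoint most-probable activation paths and Eq-style ap."""
    if prune is None:
        prune = _default_prune(cs)
    return _MoBoo(g, state, cs, lam, prune).snapshot()


def select_moboo(
    g: Graph,
    state: NetworkState,
    cs: ConceptSystem,
    k: int,
    lam: int = 2,
    prune: Union[float, int, None] = None,
) -> List[int]:
    """MoBoo seed selection adapted to the two-concept environment.

    Ranks nodes by the gain accrued over the node-disjoint most-probable
    activation paths they appear on, with the boosted edge probability
    ``p' = min(1, p * r)``.  For a boosting relationship (r > 1) the node
    with the largest gain is selected; for an inhibiting one (r < 1) the
    node with the most negative gain (largest expected loss).
    """
    if cs.r == 1.0:
        raise ValueError(
            "MoBoo gain is identically zero under a neutral relationship"
        )
    if prune is None:
        prune = _default_prune(cs)
    return _MoBoo(g, state, cs, lam, prune).select(k)


# ---------------------------------------------------------------------------
# Selector registry (heuristic handles for the cascade runner)
# ---------------------------------------------------------------------------

HEURISTIC_NAMES = (
    "random",
    "degree",
    "single_discount",
    "degree_discount",
    "moboo",
    "mpg",
)


def get_selector(name: str, k: int, **params):
    """A heuristic handle ``selector(g, state, cs, rng) -> node list``.

    ``params`` may carry ``prune`` (theta for ICM, hop limit for LTM) and
    ``lam`` for MoBoo.
    """
    if name not in HEURISTIC_NAMES:
        raise ValueError(f"unknown heuristic {name!r}; choose from {HEURISTIC_NAMES}")
    prune = params.get("prune")
    lam = params.get("lam", 2)

    def selector(g: Graph, state: NetworkState, cs: ConceptSystem, rng):
        if name == "random":
            return select_random(g, k, rng)
        if name == "degree":
            return select_degree(g, k)
        if name == "single_discount":
            return select_single_discount(g, k)
        if name == "degree_discount":
            return select_degree_discount(g, k, cs.p)
        if name == "moboo":
            return select_moboo(g, state, cs, k, lam=lam, prune=prune)
        return select_mpg(g, state, cs, k, prune=prune)

    selector.__name__ = f"select_{name}"
    return selector
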