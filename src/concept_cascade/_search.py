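"""Pruned max-product path search used by the path-based heuristics.

The influence received along a path is the product of per-edge contextual
influences; the most influential path to every node within a pruned horizon
is found by a best-first (max-product Dijkstra) search.  Because every edge
value lies in [0, 1], the first time a node is settled its product is
maximal, and expansion can stop as soon as the running product would fall
to the pruning threshold, making the search exact within the horizon.

Two implementations are provided with identical semantics: a compiled
kernel (numba) on CSR arrays used on large graphs, and a plain-Python
reference used for the linear threshold model's hop-limited variant and as
a cross-check in the test-suite.
"""

from __future__ import annotations

import heapq
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numba as nb
import numpy as np

# Strictness guard for the pruning rule "product > theta": floating-point
# products that equal theta mathematically (e.g. 0.1**3 vs 1e-3) can land a
# few ulps above it, so the comparison uses theta * (1 + 1e-9).
THETA_GUARD = 1e-9


def theta_cutoff(theta: float) -> float:
    return theta * (1.0 + THETA_GUARD)


# ---------------------------------------------------------------------------
# Compiled kernels (CSR, manual binary max-heap, stamped scratch arrays)
# ---------------------------------------------------------------------------


@nb.njit(cache=False)
def _dijkstra_kernel(
    indptr, indices, ci, src, cutoff,
    best, parent, visit_stamp, done_stamp, stamp,
    heap_p, heap_n, out_nodes,
):
    hs = 0
    heap_p[0] = 1.0
    heap_n[0] = src
    hs = 1
    best[src] = 1.0
    visit_stamp[src] = stamp
    parent[src] = -1
    count = 0
    while hs > 0:
        pr = heap_p[0]
        u = heap_n[0]
        hs -= 1
        lp = heap_p[hs]
        ln = heap_n[hs]
        i = 0
        while True:
            l = 2 * i + 1
            if l >= hs:
                break
            c = l
            rch = l + 1
            if rch < hs and (
                heap_p[rch] > heap_p[l]
                or (heap_p[rch] == heap_p[l] and heap_n[rch] < heap_n[l])
            ):
                c = rch
            if heap_p[c] > lp or (heap_p[c] == lp and heap_n[c] < ln):
                heap_p[i] = heap_p[c]
                heap_n[i] = heap_n[c]
                i = c
            else:
                break
        if hs > 0:
            heap_p[i] = lp
            heap_n[i] = ln
        if done_stamp[u] == stamp:
            continue
        if visit_stamp[u] != stamp or pr < best[u]:
            continue
        done_stamp[u] = stamp
        if u != src:
            out_nodes[count] = u
            count += 1
        for e in range(indptr[u], indptr[u + 1]):
            v = indices[e]
            npf = pr * ci[e]
            if npf > cutoff:
                if visit_stamp[v] != stamp or npf > best[v]:
                    best[v] = npf
                    visit_stamp[v] = stamp
                    parent[v] = u
                    j = hs
                    hs += 1
                    while j > 0:
                        par = (j - 1) // 2
                        if heap_p[par] < npf or (
                            heap_p[par] == npf and heap_n[par] > v
                        ):
                            heap_p[j] = heap_p[par]
                            heap_n[j] = heap_n[par]
                            j = par
                        else:
                            break
                    heap_p[j] = npf
                    heap_n[j] = v
    return count


@nb.njit(cache=False)
def _dijkstra_tree_kernel(
    indptr, indices, ci, src, cutoff,
    best, parent, peidx, visit_stamp, done_stamp, stamp,
    heap_p, heap_n, out_nodes,
):
    """Like :func:`_dijkstra_kernel` but also records, per settled node, the
    CSR data index of the tree edge from its parent (for later product
    re-evaluation under a changed edge context)."""
    hs = 0
    heap_p[0] = 1.0
    heap_n[0] = src
    hs = 1
    best[src] = 1.0
    visit_stamp[src] = stamp
    parent[src] = -1
    peidx[src] = -1
    count = 0
    while hs > 0:
        pr = heap_p[0]
        u = heap_n[0]
        hs -= 1
        lp = heap_p[hs]
        ln = heap_n[hs]
        i = 0
        while True:
            l = 2 * i + 1
            if l >= hs:
                break
            c = l
            rch = l + 1
            if rch < hs and (
                heap_p[rch] > heap_p[l]
                or (heap_p[rch] == heap_p[l] and heap_n[rch] < heap_n[l])
            ):
                c = rch
            if heap_p[c] > lp or (heap_p[c] == lp and heap_n[c] < ln):
                heap_p[i] = heap_p[c]
                heap_n[i] = heap_n[c]
                i = c
            else:
                break
        if hs > 0:
            heap_p[i] = lp
            heap_n[i] = ln
        if done_stamp[u] == stamp:
            continue
        if visit_stamp[u] != stamp or pr < best[u]:
            continue
        done_stamp[u] = stamp
        if u != src:
            out_nodes[count] = u
            count += 1
        for e in range(indptr[u], indptr[u + 1]):
            v = indices[e]
            npf = pr * ci[e]
            if npf > cutoff:
                if visit_stamp[v] != stamp or npf > best[v]:
                    best[v] = npf
                    visit_stamp[v] = stamp
                    parent[v] = u
                    peidx[v] = e
                    j = hs
                    hs += 1
                    while j > 0:
                        par = (j - 1) // 2
                        if heap_p[par] < npf or (
                            heap_p[par] == npf and heap_n[par] > v
                        ):
                            heap_p[j] = heap_p[par]
                            heap_n[j] = heap_n[par]
                            j = par
                        else:
                            break
                    heap_p[j] = npf
                    heap_n[j] = v
    return count


@nb.njit(cache=False)
def _count_batch_kernel(
    indptr, indices, ci, sources, cutoff,
    best, parent, visit_stamp, done_stamp, stamp0,
    heap_p, heap_n, out_nodes, counts,
):
    stamp = stamp0
    for i in range(sources.size):
        stamp += 1
        counts[i] = _dijkstra_kernel(
            indptr, indices, ci, sources[i], cutoff,
            best, parent, visit_stamp, done_stamp, stamp,
            heap_p, heap_n, out_nodes,
        )
    return stamp


@nb.njit(cache=False)
def _tree_batch_kernel(
    indptr, indices, ci, sources, cutoff,
    best, parent, peidx, visit_stamp, done_stamp, stamp0,
    heap_p, heap_n, out_nodes, loc,
    toffsets, tnode, tparent_pos, teidx, tprod, evals,
):
    """Run the search per source and store each pruned arborescence flat:
    position ``toffsets[i]`` holds the root (product 1, parent -1), the
    settled nodes follow in pop order so a node's parent always precedes
    it.  ``evals[i]`` is the root-excluded product sum, i.e. E(source)."""
    stamp = stamp0
    for i in range(sources.size):
        stamp += 1
        src = sources[i]
        cnt = _dijkstra_tree_kernel(
            indptr, indices, ci, src, cutoff,
            best, parent, peidx, visit_stamp, done_stamp, stamp,
            heap_p, heap_n, out_nodes,
        )
        base = toffsets[i]
        tnode[base] = src
        tparent_pos[base] = -1
        teidx[base] = -1
        tprod[base] = 1.0
        loc[src] = base
        total = 0.0
        for j in range(cnt):
            u = out_nodes[j]
            pos = base + 1 + j
            tnode[pos] = u
            loc[u] = pos
            tparent_pos[pos] = loc[parent[u]]
            teidx[pos] = peidx[u]
            tprod[pos] = best[u]
            total += best[u]
        evals[i] = total
    return stamp


@nb.njit(cache=False)
def _refresh_trees_kernel(
    tids, toffsets, tcounts, tnode, tparent_pos, teidx, tprod,
    ci, cutoff, evals, ap_arr, track_ap,
):
    """Re-evaluate stored path products of the given trees under the
    current edge context; entries at or below the pruning cutoff
    contribute zero.  With ``track_ap`` the per-node received-influence
    sums are adjusted by the contribution deltas."""
    for idx in range(tids.size):
        tid = tids[idx]
        base = toffsets[tid]
        cnt = tcounts[tid]
        total = 0.0
        for pos in range(base + 1, base + cnt):
            prod = 1.0
            x = pos
            while tparent_pos[x] != -1:
                prod *= ci[teidx[x]]
                x = tparent_pos[x]
            old = tprod[pos]
            if track_ap:
                oldc = old if old > cutoff else 0.0
                newc = prod if prod > cutoff else 0.0
                if newc != oldc:
                    ap_arr[tnode[pos]] += newc - oldc
            tprod[pos] = prod
            if prod > cutoff:
                total += prod
        evals[tid] = total


@nb.njit(cache=False)
def _e_batch_kernel(
    indptr, indices, ci, sources, cutoff,
    best, parent, visit_stamp, done_stamp, stamp0,
    heap_p, heap_n, out_nodes, evals,
):
    stamp = stamp0
    for i in range(sources.size):
        stamp += 1
        cnt = _dijkstra_kernel(
            indptr, indices, ci, sources[i], cutoff,
            best, parent, visit_stamp, done_stamp, stamp,
            heap_p, heap_n, out_nodes,
        )
        total = 0.0
        for j in range(cnt):
            total += best[out_nodes[j]]
        evals[i] = total
    return stamp


class IcmInfluenceSearch:
    """Stateful ICM path-search workspace over an undirected graph.

    Maintains the per-edge contextual influence array for the target
    concept under the current controllable-concept context; edge values are
    refreshed incrementally as nodes acquire the controllable concept via
    :meth:`activate_s`.
    """

    def __init__(self, graph, p: float, r: float, theta: float):
        if not 0.0 < theta < 1.0:
            raise ValueError("theta must lie strictly between 0 and 1")
        if graph.directed:
            raise ValueError("the compiled ICM search requires an undirected graph")
        indptr, indices = graph.csr()
        self.indptr = indptr
        self.indices = indices
        self.n = graph.n_nodes
        self.p = float(p)
        self.r = float(r)
        self.theta = float(theta)
        self.cutoff = theta_cutoff(theta)
        self.s_flags = np.zeros(self.n, dtype=np.uint8)
        self.rows = np.repeat(
            np.arange(self.n, dtype=np.int32), np.diff(indptr).astype(np.int64)
        )
        self.ci = np.full(indices.size, min(1.0, self.p), dtype=np.float64)
        order = np.argsort(indices, kind="stable")
        self._col_pos = order
        self._col_ptr = np.searchsorted(indices[order], np.arange(self.n + 1))
        # stamped scratch
        self._best = np.zeros(self.n, dtype=np.float64)
        self._parent = np.full(self.n, -1, dtype=np.int32)
        self._visit = np.zeros(self.n, dtype=np.int64)
        self._done = np.zeros(self.n, dtype=np.int64)
        cap = indices.size + 2
        self._heap_p = np.zeros(cap, dtype=np.float64)
        self._heap_n = np.zeros(cap, dtype=np.int32)
        self._out = np.zeros(max(self.n, 1), dtype=np.int32)
        self._stamp = 0

    # -- context -------------------------------------------------------

    def activate_s(self, node: int) -> None:
        """Mark ``node`` as carrying the controllable concept and refresh
        the contextual influence of its incident edges."""
        if self.s_flags[node]:
            return
        self.s_flags[node] = 1
        row = np.arange(self.indptr[node], self.indptr[node + 1])
        col = self._col_pos[self._col_ptr[node]:self._col_ptr[node + 1]]
        pos = np.concatenate([row, col])
        k = (
            self.s_flags[self.rows[pos]].astype(np.float64)
            + self.s_flags[self.indices[pos]].astype(np.float64)
        )
        self.ci[pos] = np.minimum(1.0, self.p * np.power(self.r, k))

    def edge_ci(self, u: int, v: int) -> float:
        lo, hi = self.indptr[u], self.indptr[u + 1]
        e = lo + np.searchsorted(self.indices[lo:hi], v)
        if e >= hi or self.indices[e] != v:
            raise KeyError(f"no edge ({u}, {v})")
        return float(self.ci[e])

    # -- searches --------------------------------------------------------

    def reach(self, src: int, with_paths: bool = False):
        """Nodes with IR(src, u) > theta, their IR values and (optionally)
        the most influential path realising each value."""
        self._stamp += 1
        cnt = _dijkstra_kernel(
            self.indptr, self.indices, self.ci, np.int32(src), self.cutoff,
            self._best, self._parent, self._visit, self._done, self._stamp,
            self._heap_p, self._heap_n, self._out,
        )
        nodes = self._out[:cnt].astype(np.int64)
        prods = self._best[nodes].copy()
        if not with_paths:
            return nodes, prods, None
        parents = {int(u): int(self._parent[u]) for u in nodes}
        parents[int(src)] = -1
        paths = {int(u): reconstruct_path(parents, int(src), int(u)) for u in nodes}
        return nodes, prods, paths

    def reverse_reach(self, v: int) -> np.ndarray:
        """Nodes u with IR(u, v) > theta.  The graph is undirected and the
        contextual edge values are endpoint-symmetric, so this equals the
        forward reach of v."""
        nodes, _, _ = self.reach(v)
        return nodes

    def e_values(self, sources: Sequence[int]) -> np.ndarray:
        """Expected-gain values E(u) = sum of IR(u, w) for each source."""
        src = np.asarray(sources, dtype=np.int32)
        evals = np.empty(src.size, dtype=np.float64)
        if src.size:
            self._stamp = _e_batch_kernel(
                self.indptr, self.indices, self.ci, src, self.cutoff,
                self._best, self._parent, self._visit, self._done, self._stamp,
                self._heap_p, self._heap_n, self._out, evals,
            )
        return evals

    def build_forest(self, sources: Sequence[int]) -> "FrozenForest":
        """Pruned most-influential-path arborescences for the sources."""
        return FrozenForest(self, np.asarray(sources, dtype=np.int32))


class FrozenForest:
    """Flat storage of theta-pruned arborescences with frozen structure.

    The trees are grown once; afterwards :meth:`refresh` re-evaluates the
    stored path products under the workspace's current edge context (the
    theta filter is reapplied at summation), without re-routing paths or
    re-growing the horizon.  ``evals[i]`` always holds the root-excluded,
    theta-filtered product sum of tree ``i``.
    """

    def __init__(self, ws: IcmInfluenceSearch, sources: np.ndarray):
        self.ws = ws
        self.sources = sources
        nsrc = sources.size
        counts = np.zeros(nsrc, dtype=np.int64)
        if nsrc:
            ws._stamp = _count_batch_kernel(
                ws.indptr, ws.indices, ws.ci, sources, ws.cutoff,
                ws._best, ws._parent, ws._visit, ws._done, ws._stamp,
                ws._heap_p, ws._heap_n, ws._out, counts,
            )
        self.tcounts = counts + 1  # root included
        self.toffsets = np.zeros(nsrc, dtype=np.int64)
        np.cumsum(self.tcounts[:-1], out=self.toffsets[1:])
        total = int(self.tcounts.sum())
        self.tnode = np.zeros(total, dtype=np.int32)
        self.tparent_pos = np.zeros(total, dtype=np.int64)
        self.teidx = np.zeros(total, dtype=np.int64)
        self.tprod = np.zeros(total, dtype=np.float64)
        self.evals = np.zeros(nsrc, dtype=np.float64)
        if nsrc:
            peidx = np.full(ws.n, -1, dtype=np.int64)
            loc = np.zeros(ws.n, dtype=np.int64)
            ws._stamp = _tree_batch_kernel(
                ws.indptr, ws.indices, ws.ci, sources, ws.cutoff,
                ws._best, ws._parent, peidx, ws._visit, ws._done, ws._stamp,
                ws._heap_p, ws._heap_n, ws._out, loc,
                self.toffsets, self.tnode, self.tparent_pos, self.teidx,
                self.tprod, self.evals,
            )
        # reverse index: graph node -> tree ids with that node as an entry
        entry_mask = np.ones(total, dtype=bool)
        entry_mask[self.toffsets] = False  # roots excluded
        entry_nodes = self.tnode[entry_mask]
        entry_tids = np.repeat(
            np.arange(nsrc, dtype=np.int64), self.tcounts - 1
        )
        order = np.argsort(entry_nodes, kind="stable")
        self._rev_tids = entry_tids[order]
        self._rev_ptr = np.searchsorted(
            entry_nodes[order], np.arange(ws.n + 1)
        )
        # tree id owned by each root node (-1 if none)
        self._own = np.full(ws.n, -1, dtype=np.int64)
        self._own[sources] = np.arange(nsrc, dtype=np.int64)

    def received_sums(self) -> np.ndarray:
        """Per-node sum of stored (theta-filtered) products over all trees."""
        ap = np.zeros(self.ws.n, dtype=np.float64)
        mask = self.tprod > self.ws.cutoff
        mask[self.toffsets] = False
        np.add.at(ap, self.tnode[mask], self.tprod[mask])
        return ap

    def trees_containing(self, node: int, include_own: bool = True) -> np.ndarray:
        tids = self._rev_tids[self._rev_ptr[node]:self._rev_ptr[node + 1]]
        own = self._own[node]
        if include_own and own >= 0:
            tids = np.append(tids, own)
        return np.unique(tids)

    def refresh(self, tids: np.ndarray, ap_arr: Optional[np.ndarray] = None) -> None:
        """Re-evaluate stored products of the given trees; optionally
        maintain the per-node received-influence sums in ``ap_arr``."""
        if tids.size == 0:
            return
        track = ap_arr is not None
        if ap_arr is None:
            ap_arr = np.zeros(1, dtype=np.float64)
        _refresh_trees_kernel(
            np.asarray(tids, dtype=np.int64), self.toffsets, self.tcounts,
            self.tnode, self.tparent_pos, self.teidx, self.tprod,
            self.ws.ci, self.ws.cutoff, self.evals, ap_arr, track,
        )


# ---------------------------------------------------------------------------
# Plain-Python reference searches
# ---------------------------------------------------------------------------


def maxprod_dijkstra_py(
    out_neighbors: Callable[[int], Iterable[int]],
    edge_ci: Callable[[int, int], float],
    src: int,
    theta: float,
) -> Tuple[Dict[int, float], Dict[int, int]]:
    """Theta-pruned max-product search; returns (ir, parent) maps."""
    cutoff = theta_cutoff(theta)
    best: Dict[int, float] = {src: 1.0}
    parent: Dict[int, int] = {src: -1}
    done: set = set()
    heap: List[Tuple[float, int]] = [(-1.0, src)]
    while heap:
        negp, u = heapq.heappop(heap)
        pr = -negp
        if u in done or pr < best.get(u, 0.0):
            continue
        done.add(u)
        for v in sorted(out_neighbors(u)):
            npf = pr * edge_ci(u, v)
            if npf > cutoff and npf > best.get(v, 0.0):
                best[v] = npf
                parent[v] = u
                heapq.heappush(heap, (-npf, v))
    best.pop(src)
    parent.pop(src)
    return best, parent


def maxprod_hoplimit_py(
    out_neighbors: Callable[[int], Iterable[int]],
    edge_ci: Callable[[int, int], float],
    src: int,
    hop_limit: int,
) -> Tuple[Dict[int, float], Dict[int, List[int]]]:
    """Hop-limited max-product search (exact within ``hop_limit`` hops).

    Dynamic programme over (node, hop) states; ties between equal products
    keep the fewer-hop path, which also keeps reconstructed paths simple.
    Returns (ir, path) maps where each path runs from ``src`` to the node.
    """
    if hop_limit < 1:
        raise ValueError("hop limit must be at least 1")
    layers: List[Dict[int, float]] = [dict() for _ in range(hop_limit + 1)]
    layers[0][src] = 1.0
    parent: Dict[Tuple[int, int], int] = {}
    for h in range(1, hop_limit + 1):
        for u, pu in sorted(layers[h - 1].items()):
            for v in sorted(out_neighbors(u)):
                val = pu * edge_ci(u, v)
                if val > 0.0 and val > layers[h].get(v, 0.0):
                    layers[h][v] = val
                    parent[(v, h)] = u
    ir: Dict[int, float] = {}
    best_hop: Dict[int, int] = {}
    for h in range(1, hop_limit + 1):
        for v, val in layers[h].items():
            if v != src and val > ir.get(v, 0.0):
                ir[v] = val
                best_hop[v] = h
    paths: Dict[int, List[int]] = {}
    for v, h in best_hop.items():
        path = [v]
        node, hop = v, h
        while hop > 0:
            node = parent[(node, hop)]
            hop -= 1
            path.append(node)
        paths[v] = path[::-1]
    return ir, paths


class ReferenceInfluenceSearch:
    """Pure-Python counterpart of :class:`IcmInfluenceSearch`.

    Also covers the LTM, where pruning is a hop limit rather than an
    influence threshold and edge values are threshold-normalised weights.
    Slower but model-agnostic and directionality-aware.
    """

    def __init__(self, graph, cs, prune, target_concept_context: bool = True):
        from .interaction import ICM as _ICM

        self.graph = graph
        self.cs = cs
        self.model = cs.model_tag
        self.prune = prune
        if self.model == _ICM and not 0.0 < prune < 1.0:
            raise ValueError("theta must lie strictly between 0 and 1")
        self.s_active = np.zeros(graph.n_nodes, dtype=bool)

    def seed_context(self, s_nodes: Iterable[int]) -> None:
        for u in s_nodes:
            self.s_active[u] = True

    def activate_s(self, node: int) -> None:
        self.s_active[node] = True

    def edge_ci(self, u: int, v: int) -> float:
        from .interaction import ICM as _ICM
        from .interaction import contextual_influence, influence_strength_ltm

        if self.model == _ICM:
            base = self.cs.p
        else:
            base = influence_strength_ltm(
                self.graph.ltm_weight(u, v, self.cs.target_id),
                self.graph.ltm_threshold(v, self.cs.target_id),
            )
        return contextual_influence(
            base, bool(self.s_active[u]), bool(self.s_active[v]), self.cs.r
        )

    def _reverse_edge_ci(self, u: int, v: int) -> float:
        # value of the forward edge (v, u), explored backwards
        return self.edge_ci(v, u)

    def reach(self, src: int, with_paths: bool = False):
        from .interaction import ICM as _ICM

        paths: Optional[Dict[int, Tuple[int, ...]]] = None
        if self.model == _ICM:
            ir, parent = maxprod_dijkstra_py(
                self.graph.out_neighbors, self.edge_ci, src, self.prune
            )
            if with_paths:
                parent = dict(parent)
                parent[src] = -1
                paths = {v: reconstruct_path(parent, src, v) for v in ir}
        else:
            ir, raw_paths = maxprod_hoplimit_py(
                self.graph.out_neighbors, self.edge_ci, src, self.prune
            )
            if with_paths:
                paths = {v: tuple(path) for v, path in raw_paths.items()}
        nodes = np.array(sorted(ir), dtype=np.int64)
        prods = np.array([ir[v] for v in nodes], dtype=np.float64)
        if not with_paths:
            return nodes, prods, None
        return nodes, prods, paths

    def reverse_reach(self, v: int) -> np.ndarray:
        from .interaction import ICM as _ICM

        if self.model == _ICM:
            ir, _ = maxprod_dijkstra_py(
                self.graph.in_neighbors, self._reverse_edge_ci, v, self.prune
            )
        else:
            ir, _ = maxprod_hoplimit_py(
                self.graph.in_neighbors, self._reverse_edge_ci, v, self.prune
            )
        return np.array(sorted(ir), dtype=np.int64)

    def e_values(self, sources: Sequence[int]) -> np.ndarray:
        out = np.empty(len(sources), dtype=np.float64)
        for i, u in enumerate(sources):
            _, prods, _ = self.reach(int(u))
            out[i] = float(prods.sum())
        return out


def reconstruct_path(parents: Dict[int, int], src: int, node: int) -> Tuple[int, ...]:
    """Chase a parent map back from ``node`` to ``src``."""
    path = [node]
    while path[-1] != src:
        path.append(parents[path[-1]])
    return tuple(reversed(path))
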