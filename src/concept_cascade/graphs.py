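"""Synthetic network generators and edge-list I/O.

Two network families are used throughout: Kleinberg-style small-world
networks (a toroidal lattice with distance-biased long-range shortcuts)
and Barabási–Albert style scale-free networks grown by preferential
attachment from an initially unconnected seed population.  Graphs may
additionally carry linear-threshold-model (LTM) attributes: a per-node,
per-concept activation threshold and a per-edge, per-concept influence
weight.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Graph",
    "generate_small_world",
    "generate_scale_free",
    "assign_ltm_attributes",
    "load_edge_list",
    "write_edge_list",
]


class Graph:
    """A simple/directed graph with optional per-concept LTM attributes.

    Nodes are the integers ``0 .. n_nodes - 1``.  For undirected graphs an
    edge is stored once as an unordered pair but exposed in both influence
    directions.  Self-loops and duplicate edges are rejected.
    """

    def __init__(self, n_nodes: int, directed: bool = False):
        if n_nodes < 0:
            raise ValueError("node count must be nonnegative")
        self._n = int(n_nodes)
        self.directed = bool(directed)
        self._adj_out: List[List[int]] = [[] for _ in range(self._n)]
        self._adj_in: List[List[int]] = self._adj_out if not directed else [
            [] for _ in range(self._n)
        ]
        self._edge_set: set = set()
        # LTM attributes: thresholds[c] is an (n,) array, weights[c] maps
        # directed (v, u) pairs to the influence weight exerted by v on u.
        self.thresholds: Optional[Dict[str, np.ndarray]] = None
        self.weights: Optional[Dict[str, Dict[Tuple[int, int], float]]] = None
        self._csr_cache: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # -- construction -------------------------------------------------

    def _canon(self, u: int, v: int) -> Tuple[int, int]:
        if self.directed:
            return (u, v)
        return (u, v) if u < v else (v, u)

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if not (0 <= u < self._n and 0 <= v < self._n):
            raise ValueError(f"edge ({u}, {v}) references a missing node")
        key = self._canon(u, v)
        if key in self._edge_set:
            raise ValueError(f"duplicate edge ({u}, {v})")
        self._edge_set.add(key)
        self._adj_out[u].append(v)
        if self.directed:
            self._adj_in[v].append(u)
        else:
            self._adj_out[v].append(u)
        self._csr_cache = None

    def has_edge(self, u: int, v: int) -> bool:
        return self._canon(u, v) in self._edge_set

    # -- queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._n

    @property
    def n_edges(self) -> int:
        return len(self._edge_set)

    def nodes(self) -> range:
        return range(self._n)

    def edges(self) -> Iterator[Tuple[int, int]]:
        return iter(sorted(self._edge_set))

    def out_neighbors(self, u: int) -> List[int]:
        return self._adj_out[u]

    def in_neighbors(self, u: int) -> List[int]:
        return self._adj_in[u]

    def out_degree(self, u: int) -> int:
        return len(self._adj_out[u])

    def in_degree(self, u: int) -> int:
        return len(self._adj_in[u])

    def degree(self, u: int) -> int:
        if self.directed:
            return len(self._adj_out[u]) + len(self._adj_in[u])
        return len(self._adj_out[u])

    def degrees(self) -> np.ndarray:
        return np.array([self.degree(u) for u in range(self._n)], dtype=np.int64)

    def csr(self) -> Tuple[np.ndarray, np.ndarray]:
        """Out-adjacency in CSR form: (indptr int64, indices int32)."""
        if self._csr_cache is None:
            counts = np.array([len(a) for a in self._adj_out], dtype=np.int64)
            indptr = np.zeros(self._n + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            indices = np.empty(int(indptr[-1]), dtype=np.int32)
            for u, nbrs in enumerate(self._adj_out):
                indices[indptr[u]:indptr[u + 1]] = sorted(nbrs)
            self._csr_cache = (indptr, indices)
        return self._csr_cache

    def is_connected(self) -> bool:
        if self._n == 0:
            return True
        indptr, indices = self.csr()
        seen = np.zeros(self._n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for v in indices[indptr[u]:indptr[u + 1]]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        return bool(seen.all())

    # -- LTM attributes --------------------------------------------------

    def has_ltm_attributes(self) -> bool:
        return self.thresholds is not None and self.weights is not None

    def ltm_threshold(self, u: int, concept: str) -> float:
        if self.thresholds is None:
            raise ValueError("graph carries no LTM thresholds")
        return float(self.thresholds[concept][u])

    def ltm_weight(self, v: int, u: int, concept: str) -> float:
        if self.weights is None:
            raise ValueError("graph carries no LTM weights")
        return self.weights[concept].get((v, u), 0.0)

    def validate_ltm(self, tol: float = 1e-9) -> None:
        """Check the LTM invariants: incoming weights sum to 1 per concept."""
        if not self.has_ltm_attributes():
            raise ValueError("graph carries no LTM attributes")
        for c, wtab in self.weights.items():
            for u in range(self._n):
                nbrs = self.in_neighbors(u)
                if not nbrs:
                    continue
                total = sum(wtab[(v, u)] for v in nbrs)
                if abs(total - 1.0) > tol:
                    raise AssertionError(
                        f"incoming weights for node {u}, concept {c!r} "
                        f"sum to {total}, expected 1"
                    )


# ---------------------------------------------------------------------------
# Small-world generator
# ---------------------------------------------------------------------------


def _lattice_shape(n: int, max_aspect: float = 4.0) -> Tuple[int, int]:
    """Most-square factorisation rows*cols == n with rows <= cols."""
    best = None
    for rows in range(int(math.isqrt(n)), 0, -1):
        if n % rows == 0:
            best = (rows, n // rows)
            break
    assert best is not None
    rows, cols = best
    if cols > max_aspect * rows:
        raise ValueError("lattice shape infeasible")
    return rows, cols


def _toroidal_offsets(rows: int, cols: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All nonzero (dr, dc) offsets and their toroidal Manhattan distances."""
    dr = np.repeat(np.arange(rows), cols)
    dc = np.tile(np.arange(cols), rows)
    dist = np.minimum(dr, rows - dr) + np.minimum(dc, cols - dc)
    keep = dist > 0
    return dr[keep], dc[keep], dist[keep]


def generate_small_world(
    n: int,
    clustering_exponent: float,
    long_range_per_node: int = 1,
    rng_seed: int = 0,
) -> Graph:
    """Kleinberg-style small-world network on a toroidal lattice.

    Every node sits on a rows x cols torus (most-square factorisation of
    ``n``) and is linked to its 4 von Neumann lattice neighbours.  Each node
    additionally sources ``long_range_per_node`` shortcut edges whose targets
    are drawn with probability proportional to d(u, v)**(-clustering_exponent),
    d being toroidal Manhattan distance; draws landing on the node itself or
    on an existing edge are resampled.  The graph is undirected.
    """
    if n < 4:
        raise ValueError("small-world networks need at least 4 nodes")
    if clustering_exponent < 0:
        raise ValueError("clustering exponent must be nonnegative")
    if long_range_per_node < 0:
        raise ValueError("long-range edge count must be nonnegative")
    rows, cols = _lattice_shape(n)
    g = Graph(n)

    def nid(r: int, c: int) -> int:
        return (r % rows) * cols + (c % cols)

    edge_set = set()
    for r in range(rows):
        for c in range(cols):
            u = nid(r, c)
            for v in (nid(r + 1, c), nid(r, c + 1)):
                if u != v:
                    key = (u, v) if u < v else (v, u)
                    edge_set.add(key)

    if long_range_per_node > 0:
        rng = np.random.default_rng(rng_seed)
        dr, dc, dist = _toroidal_offsets(rows, cols)
        weights = dist.astype(np.float64) ** (-float(clustering_exponent))
        weights /= weights.sum()
        cdf = np.cumsum(weights)
        cdf[-1] = 1.0
        draws = np.searchsorted(cdf, rng.random(n * long_range_per_node), side="right")
        i = 0
        for u in range(n):
            ur, uc = divmod(u, cols)
            for _ in range(long_range_per_node):
                while True:
                    if i < len(draws):
                        k = int(draws[i])
                        i += 1
                    else:  # resample on self/duplicate collision
                        k = int(np.searchsorted(cdf, rng.random(), side="right"))
                    v = nid(ur + int(dr[k]), uc + int(dc[k]))
                    key = (u, v) if u < v else (v, u)
                    if key not in edge_set:
                        edge_set.add(key)
                        break

    for u, v in edge_set:
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Scale-free generator
# ---------------------------------------------------------------------------

_SEED_NODES = 10  # initially unconnected nodes


def generate_scale_free(n: int, m: int, rng_seed: int = 0) -> Graph:
    """Barabási–Albert style preferential-attachment network.

    Starts from 10 isolated nodes; each of the remaining ``n - 10`` evolution
    steps introduces one node with ``m`` distinct edges whose endpoints are
    drawn with probability proportional to (degree + 1).  The +1 smoothing
    lets the initially unconnected seed nodes acquire edges; duplicate draws
    within one step are resampled.
    """
    if n < _SEED_NODES:
        raise ValueError(f"scale-free networks need at least {_SEED_NODES} nodes")
    if m < 1:
        raise ValueError("m must be positive")
    if m >= _SEED_NODES:
        raise ValueError("m must be smaller than the current node count")
    rng = np.random.default_rng(rng_seed)
    g = Graph(n)
    # attachment multiset: node u appears degree(u) + 1 times
    total_slots = _SEED_NODES + (n - _SEED_NODES) * (2 * m + 1)
    attach = np.empty(total_slots, dtype=np.int32)
    attach[:_SEED_NODES] = np.arange(_SEED_NODES)
    fill = _SEED_NODES
    for new in range(_SEED_NODES, n):
        chosen: set = set()
        while len(chosen) < m:
            t = int(attach[int(rng.integers(0, fill))])
            if t not in chosen:
                chosen.add(t)
        for t in sorted(chosen):
            g.add_edge(new, t)
            attach[fill] = t
            fill += 1
        attach[fill:fill + m + 1] = new
        fill += m + 1
    return g


# ---------------------------------------------------------------------------
# LTM attribute assignment
# ---------------------------------------------------------------------------

_THRESHOLD_FLOOR = 0.05  # clamp for Gaussian tails


def assign_ltm_attributes(
    g: Graph,
    concepts: Sequence[str],
    threshold_mean: float = 0.8,
    threshold_sd: float = 0.05,
    rng_seed: int = 0,
) -> Graph:
    """Draw per-node thresholds and set uniform 1/in-degree edge weights.

    Thresholds are i.i.d. Normal(mean, sd) clamped to [0.05, 1] for every
    (node, concept) pair.  Each incoming edge of node ``u`` receives weight
    ``1 / in_degree(u)`` for every concept, the canonical LTM weighting, so
    that incoming weights sum to one.  Modifies ``g`` in place and returns it.
    """
    if g.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    if threshold_sd < 0:
        raise ValueError("threshold standard deviation must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    g.thresholds = {}
    g.weights = {}
    for c in concepts:
        th = rng.normal(threshold_mean, threshold_sd, size=g.n_nodes)
        g.thresholds[c] = np.clip(th, _THRESHOLD_FLOOR, 1.0)
        wtab: Dict[Tuple[int, int], float] = {}
        for u in range(g.n_nodes):
            nbrs = g.in_neighbors(u)
            if nbrs:
                w = 1.0 / len(nbrs)
                for v in nbrs:
                    wtab[(v, u)] = w
        g.weights[c] = wtab
    return g


# ---------------------------------------------------------------------------
# Edge-list I/O (SNAP-style whitespace-separated, '#' comments)
# ---------------------------------------------------------------------------


def load_edge_list(path, directed: bool = False) -> Graph:
    """Read a plain-text edge list: one ``u v`` pair per line, '#' comments."""
    edges = []
    max_id = -1
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge list line {lineno}: {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(
                    f"malformed edge list line {lineno}: {line!r}"
                ) from None
            if u < 0 or v < 0:
                raise ValueError(f"negative node id at line {lineno}")
            edges.append((u, v))
            max_id = max(max_id, u, v)
    if not edges:
        raise ValueError(f"edge list {path} contains no edges")
    g = Graph(max_id + 1, directed=directed)
    for u, v in edges:
        if not g.has_edge(u, v):
            g.add_edge(u, v)
    return g


def write_edge_list(g: Graph, path) -> None:
    """Write the canonical edge list: ascending ``u v`` pairs, one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")
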