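"""Independent oracles used to freeze expected values in the tests.

These deliberately avoid the package's search/selection code paths:
influence tables are checked against exhaustive simple-path enumeration,
degree discount against a quadratic from-scratch re-evaluation of the
score formula, and Welch p-values against the textbook statistic.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Tuple

import numpy as np
from scipy import stats


def enumerate_best_paths(
    out_neighbors: Callable[[int], List[int]],
    nodes: List[int],
    edge_ci: Callable[[int, int], float],
    source: int,
    cutoff: float,
) -> Dict[int, Tuple[float, Tuple[int, ...]]]:
    """Best product over ALL simple paths from source, by brute force.

    Only destinations whose best product exceeds ``cutoff`` are returned.
    Suitable for graphs of up to ~8 nodes.
    """
    best: Dict[int, Tuple[float, Tuple[int, ...]]] = {}

    def dfs(path: List[int], prod: float) -> None:
        u = path[-1]
        for v in out_neighbors(u):
            if v in path:
                continue
            npf = prod * edge_ci(u, v)
            if npf <= cutoff:
                continue
            if v not in best or npf > best[v][0]:
                best[v] = (npf, tuple(path) + (v,))
            dfs(path + [v], npf)

    dfs([source], 1.0)
    return best


def naive_degree_discount(adj: List[List[int]], k: int, p: float) -> List[int]:
    """Degree discount re-evaluated from scratch every round (quadratic)."""
    n = len(adj)
    deg = [len(a) for a in adj]
    selected: List[int] = []
    chosen = [False] * n
    for _ in range(k):
        best_u, best_score = -1, -np.inf
        for u in range(n):
            if chosen[u]:
                continue
            t = sum(1 for v in adj[u] if chosen[v])
            score = deg[u] - 2 * t - (deg[u] - t) * t * p
            if score > best_score:
                best_u, best_score = u, score
        selected.append(best_u)
        chosen[best_u] = True
    return selected


def welch_p_value(x, y) -> float:
    """Two-tailed Welch p from the textbook statistic and t CDF."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2.0 * stats.t.sf(abs(t), df))
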