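"""Synchronous two-concept cascade simulation (ICM and LTM).

The target concept spreads alone for ``burn_in`` steps, a selector is then
invoked on the observed state to place the controllable concept's seeds,
and both concepts spread synchronously until quiescence.  All transmission
probabilities within a step are evaluated against the state at the start of
that step, so a node gaining both concepts in the same step shows no
intra-step interaction.  Activation is monotone: a concept once active on a
node never deactivates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

import numpy as np

from .graphs import Graph
from .interaction import ICM, LTM, ConceptSystem, contextual_influence, influence_strength_ltm

__all__ = [
    "NetworkState",
    "CascadeResult",
    "run_icm",
    "run_ltm",
    "run_single_concept",
]

#: A controllable-concept seed source: nothing, an explicit node set, or a
#: heuristic handle called as ``selector(graph, state, concept_system, rng)``.
SeedSelector = Union[None, Iterable[int], Callable]

MAX_STEPS_DEFAULT = 10_000

logger = logging.getLogger(__name__)


@dataclass
class NetworkState:
    """Snapshot of a running cascade, handed to seed selectors.

    ``active[c]`` is a boolean node mask; ``frontier[c]`` holds the nodes
    newly activated with concept ``c`` in the previous step (for the ICM this
    is the set of nodes able to exert influence in the next step; for the LTM
    every active node keeps exerting influence).
    """

    active: Dict[str, np.ndarray]
    frontier: Dict[str, np.ndarray]
    step_index: int = 0

    def spreading_nodes(self, concept: str, model_tag: str) -> np.ndarray:
        """Nodes able to exert influence for ``concept`` in the next step."""
        if model_tag == LTM:
            return np.flatnonzero(self.active[concept])
        return self.frontier[concept]


@dataclass
class CascadeResult:
    final_active_count: Dict[str, int]
    activations_per_step: Dict[str, List[int]]
    final_active_sets: Dict[str, FrozenSet[int]]
    steps_run: int
    attempted: Optional[Dict[str, Set[Tuple[int, int]]]] = None


def _as_seed_array(seeds: Iterable[int], n: int, name: str) -> np.ndarray:
    arr = np.unique(np.asarray(sorted(set(int(x) for x in seeds)), dtype=np.int64))
    if arr.size and (arr[0] < 0 or arr[-1] >= n):
        raise ValueError(f"{name} contains node ids outside the graph")
    return arr


def _gather_neighbors(
    indptr: np.ndarray, indices: np.ndarray, frontier: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """All (source, target) out-edge pairs for the frontier, vectorised."""
    if frontier.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    counts = indptr[frontier + 1] - indptr[frontier]
    total = int(counts.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    pos = np.arange(total) - offsets + np.repeat(indptr[frontier], counts)
    return np.repeat(frontier, counts), indices[pos].astype(np.int64)


def _resolve_controllable_seeds(
    selector: SeedSelector,
    g: Graph,
    state: NetworkState,
    cs: ConceptSystem,
    rng: np.random.Generator,
) -> np.ndarray:
    if selector is None:
        return np.empty(0, dtype=np.int64)
    if callable(selector):
        chosen = selector(g, state, cs, rng)
    else:
        chosen = selector
    return _as_seed_array(chosen, g.n_nodes, "controllable seed set")


def run_icm(
    g: Graph,
    cs: ConceptSystem,
    target_seeds: Iterable[int],
    controllable_seed_selector: SeedSelector = None,
    burn_in: int = 0,
    rng_seed: int = 0,
    max_steps: int = MAX_STEPS_DEFAULT,
    record_attempts: bool = False,
) -> CascadeResult:
    """Simulate both concepts under the independent cascade model.

    Each node that activated a concept in the previous step attempts each of
    its out-edges exactly once for that concept.  The target concept succeeds
    with probability ``min(1, p * r**k)`` where ``k`` counts the interaction
    endpoints carrying the controllable concept at the start of the step; the
    controllable concept spreads at the base probability ``p``.
    """
    if burn_in < 0:
        raise ValueError("burn-in must be nonnegative")
    if max_steps < burn_in:
        raise ValueError("max_steps must be at least the burn-in time")
    t, s = cs.target_id, cs.controllable_id
    n = g.n_nodes
    seeds_t = _as_seed_array(target_seeds, n, "target seed set")
    if seeds_t.size == 0:
        raise ValueError("target seed set must be nonempty")

    indptr, indices = g.csr()
    rng = np.random.default_rng(rng_seed)
    active = {t: np.zeros(n, dtype=bool), s: np.zeros(n, dtype=bool)}
    active[t][seeds_t] = True
    frontier = {t: seeds_t, s: np.empty(0, dtype=np.int64)}
    per_step: Dict[str, List[int]] = {t: [], s: []}
    attempted: Optional[Dict[str, Set[Tuple[int, int]]]] = (
        {t: set(), s: set()} if record_attempts else None
    )
    steps = 0
    p, r = cs.p, cs.r

    def attempt(concept: str, scale_by_context: bool) -> np.ndarray:
        src, tgt = _gather_neighbors(indptr, indices, frontier[concept])
        if attempted is not None and src.size:
            pairs = list(zip(src.tolist(), tgt.tolist()))
            log = attempted[concept]
            for pair in pairs:
                if pair in log:
                    raise AssertionError(f"edge {pair} retried for {concept!r}")
                log.add(pair)
        fresh = ~active[concept][tgt]
        src, tgt = src[fresh], tgt[fresh]
        if src.size == 0:
            return np.empty(0, dtype=np.int64)
        if scale_by_context:
            k = active[s][src].astype(np.int64) + active[s][tgt].astype(np.int64)
            probs = np.minimum(1.0, p * np.power(float(r), k))
        else:
            probs = p
        hit = rng.random(src.size) < probs
        return np.unique(tgt[hit])

    # phase 1: target concept spreads alone during burn-in
    while steps < burn_in:
        new_t = attempt(t, scale_by_context=False)
        active[t][new_t] = True
        frontier[t] = new_t
        per_step[t].append(int(new_t.size))
        per_step[s].append(0)
        steps += 1

    # phase 2: select and inject controllable seeds on the observed state
    state = NetworkState(active=active, frontier=frontier, step_index=steps)
    seeds_s = _resolve_controllable_seeds(
        controllable_seed_selector, g, state, cs, rng
    )
    active[s][seeds_s] = True
    frontier[s] = seeds_s

    # phase 3: both concepts spread synchronously
    while steps < max_steps and (frontier[t].size or frontier[s].size):
        new_t = attempt(t, scale_by_context=True)
        new_s = attempt(s, scale_by_context=False)
        active[t][new_t] = True
        active[s][new_s] = True
        frontier[t] = new_t
        frontier[s] = new_s
        per_step[t].append(int(new_t.size))
        per_step[s].append(int(new_s.size))
        steps += 1
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "ICM step %d: frontier sizes t=%d s=%d",
                steps, new_t.size, new_s.size,
            )

    return CascadeResult(
        final_active_count={c: int(active[c].sum()) for c in (t, s)},
        activations_per_step=per_step,
        final_active_sets={
            c: frozenset(np.flatnonzero(active[c]).tolist()) for c in (t, s)
        },
        steps_run=steps,
        attempted=attempted,
    )


def run_ltm(
    g: Graph,
    cs: ConceptSystem,
    target_seeds: Iterable[int],
    controllable_seed_selector: SeedSelector = None,
    burn_in: int = 0,
    rng_seed: int = 0,
    max_steps: int = MAX_STEPS_DEFAULT,
) -> CascadeResult:
    """Simulate both concepts under the linear threshold model.

    An inactive node activates concept ``c`` once the summed contextual
    influence from its c-active in-neighbours reaches 1, influence being the
    edge weight normalised by the receiver's threshold and scaled by the
    concept relationship (``r`` for the target concept, 1 for the
    controllable one).  Given fixed thresholds the trajectory is
    deterministic; randomness only enters through a stochastic seed selector.
    """
    if burn_in < 0:
        raise ValueError("burn-in must be nonnegative")
    if max_steps < burn_in:
        raise ValueError("max_steps must be at least the burn-in time")
    t, s = cs.target_id, cs.controllable_id
    if not g.has_ltm_attributes():
        raise ValueError("graph carries no LTM attributes")
    for c in (t, s):
        if c not in g.thresholds or c not in g.weights:
            raise ValueError(f"graph carries no LTM attributes for concept {c!r}")
    n = g.n_nodes
    seeds_t = _as_seed_array(target_seeds, n, "target seed set")
    if seeds_t.size == 0:
        raise ValueError("target seed set must be nonempty")

    rng = np.random.default_rng(rng_seed)
    active = {t: np.zeros(n, dtype=bool), s: np.zeros(n, dtype=bool)}
    active[t][seeds_t] = True
    frontier = {t: seeds_t, s: np.empty(0, dtype=np.int64)}
    per_step: Dict[str, List[int]] = {t: [], s: []}
    steps = 0

    def step_activations(concepts: Tuple[str, ...]) -> Dict[str, np.ndarray]:
        """New activations per concept, evaluated on the start-of-step state."""
        s_active = active[s]
        new: Dict[str, List[int]] = {c: [] for c in concepts}
        for c in concepts:
            r_c = cs.r if c == t else 1.0
            th = g.thresholds[c]
            wtab = g.weights[c]
            candidates: Set[int] = set()
            for u in np.flatnonzero(active[c]):
                for v in g.out_neighbors(int(u)):
                    if not active[c][v]:
                        candidates.add(v)
            for u in sorted(candidates):
                total = 0.0
                for v in g.in_neighbors(u):
                    if active[c][v]:
                        base = influence_strength_ltm(wtab[(v, u)], th[u])
                        total += contextual_influence(
                            base, bool(s_active[v]), bool(s_active[u]), r_c
                        )
                if total >= 1.0:
                    new[c].append(u)
        return {c: np.asarray(new[c], dtype=np.int64) for c in concepts}

    while steps < burn_in:
        new = step_activations((t,))
        active[t][new[t]] = True
        frontier[t] = new[t]
        per_step[t].append(int(new[t].size))
        per_step[s].append(0)
        steps += 1

    state = NetworkState(active=active, frontier=frontier, step_index=steps)
    seeds_s = _resolve_controllable_seeds(
        controllable_seed_selector, g, state, cs, rng
    )
    active[s][seeds_s] = True
    frontier[s] = seeds_s

    while steps < max_steps:
        new = step_activations((t, s))
        if new[t].size == 0 and new[s].size == 0:
            break
        active[t][new[t]] = True
        active[s][new[s]] = True
        frontier[t] = new[t]
        frontier[s] = new[s]
        per_step[t].append(int(new[t].size))
        per_step[s].append(int(new[s].size))
        steps += 1
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "LTM step %d: frontier sizes t=%d s=%d",
                steps, new[t].size, new[s].size,
            )

    return CascadeResult(
        final_active_count={c: int(active[c].sum()) for c in (t, s)},
        activations_per_step=per_step,
        final_active_sets={
            c: frozenset(np.flatnonzero(active[c]).tolist()) for c in (t, s)
        },
        steps_run=steps,
    )


def run_single_concept(
    g: Graph,
    cs: ConceptSystem,
    seeds: Iterable[int],
    model: Optional[str] = None,
    rng_seed: int = 0,
    max_steps: int = MAX_STEPS_DEFAULT,
) -> CascadeResult:
    """One concept spreading alone: wrapper with an empty controllable set."""
    model = model or cs.model_tag
    runner = run_icm if model == ICM else run_ltm
    return runner(
        g,
        cs,
        seeds,
        controllable_seed_selector=frozenset(),
        burn_in=0,
        rng_seed=rng_seed,
        max_steps=max_steps,
    )
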