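# Methods

## Model

Two concepts spread simultaneously on a network of `n` nodes: a *target*
concept `t` (a disease, rumour or opinion whose seeds we cannot choose) and
a *controllable* concept `s` (awareness, vaccination behaviour, supporting
information) whose seed set we place.  Concepts do not block each other;
they interact through the *relationship strength* `r ∈ [0, ∞)`:
transmission influence for `t` across an edge is multiplied by `r` once for
each interaction endpoint (infector, receiver) that carries `s`, capped
at 1:

    CI(t) = min(1, I(t) · r^k),   k = [s on infector] + [s on receiver].

`r < 1` is inhibiting, `r > 1` boosting, `r = 1` neutral.  The controllable
concept itself always spreads at base rates; `t` never modifies the spread
of `s`.  A `RelationshipMatrix` generalises this to more concepts with
multiplicatively composed pairwise effects, again capped at 1 (a cap is an
activation guarantee in both spread models).

Two spread models are implemented:

- **ICM** (independent cascade): a node that activated a concept in the
  previous step attempts each out-edge exactly once for that concept,
  succeeding with probability `CI`; base influence is `p` on every edge.
- **LTM** (linear threshold): every active node exerts influence each step;
  an inactive node activates `c` once the summed contextual influence from
  its c-active in-neighbours reaches 1, where base influence per edge is
  `min(1, w/T)` — the edge weight as a fraction of the receiver's
  threshold.  Given fixed thresholds the LTM trajectory is deterministic.

Activation is permanent (no SIS/SIR-style recovery).  Updates are
synchronous: all transmission probabilities in a step are evaluated on the
state at the start of the step, so a node gaining `t` and `s`
simultaneously shows no intra-step interaction; this avoids any dependence
on within-step processing order.

**Protocol.** The target concept spreads alone for `burn_in` steps; the
seed selector is then invoked on the observed state (it may select nodes
that already carry `t`); the controllable seeds activate immediately and
both concepts spread to quiescence.  The reported outcome is the final
number of nodes with the target concept active, seeds included.  The set
`S_t` of nodes able to exert target influence at selection time is the last
burn-in frontier for the ICM (the initial seed set when `burn_in = 0`) and
every t-active node for the LTM.

## Seed-selection heuristics

*Random*, *highest degree*, *single discount* (degree minus
already-selected neighbours) and *degree discount* (score
`d_v − 2 t_v − (d_v − t_v) t_v p`, with `t_v` the selected-neighbour count)
are standard influence-maximisation baselines.  All deterministic selectors
break ties by lowest node id.

### MPG (maximum potential gain)

For every node `u` within a pruned horizon of `S_t`, the influence received
along the most influential path (maximum product of per-edge contextual
influences over simple paths) is `IR(v, u)`; values at or below the pruning
threshold count as zero.  Scores are

    ap(u) = Σ_{v∈S_t} IR(v, u)        (activation-probability surrogate)
    E(u)  = Σ_w IR(u, w)              (expected downstream activations)
    WE(u) = ap(u) · E(u),

with `E` computed only where `ap > 0`.  `E` is evaluated in the *current*
context (previously selected seeds carry `s`; the candidate itself does
not): this keeps the score meaningful for inhibiting relationships, where a
high-WE node is the most damaging place to land `s`.  The greedy loop
selects the WE-argmax, marks it s-active, and updates affected scores; when
every remaining WE is zero it falls back to lowest node id.

**Pruning.** ICM: expansion stops once the running product is no longer
strictly above `θ` (default 0.001; with `p = 0.1` this is the 2-hop
neighbourhood before any boost).  LTM: influence values vary too much for a
product cutoff, so exploration is limited to 3 hops (path node-length 4).
Because edge values lie in [0, 1], best-first max-product search is exact
within the pruned horizon.

**Fixed-arborescence updates.**  The pruned most-influential-path trees
(for `ap`, one per `S_t` source; for `E`, one per scored node) are built
once when scoring is initialised.  After each selection, the stored path
products are re-evaluated under the updated edge context and the pruning
filter is reapplied; paths are not re-routed and the horizon is not
re-grown.  This is the design used throughout the PMIA family of influence
estimators, from which MPG descends.  The alternative — a fresh search for
every invalidated score — is combinatorially explosive on scale-free
networks: selections concentrate on hubs, a hub sits in the pruned horizon
of more than half the scored nodes, and boosted edges keep enlarging every
search ball; profiling showed this growing past tens of seconds *per
selection* at n = 25 000, m = 4.  Frozen trees bound each update by the
stored tree sizes and change selections only through second-order effects
(missed path re-routing and horizon growth).

Two implementations share these semantics: a compiled kernel (numba, CSR
arrays, stamped scratch) and a pure-Python reference that also covers the
LTM and directed graphs.  Both use the same deterministic tie rules
(heap ordered by product, then lowest node id; neighbours scanned in
ascending order), and the test-suite checks they return identical
selections on graphs with dyadic probabilities, where every product is
exactly representable.

### MoBoo

The comparator heuristic ranks nodes by gain over node-disjoint
most-probable activation paths.  For each node `v`, the best path from each
spreading source is a candidate; up to `λ` (default 2) candidates sharing
only the end node (and possibly the start node) are kept, giving
`ap(v) = 1 − Π_i (1 − P(μ^i(v)))`.  The gain of `v` accumulates
`(min(1, p_e·r)/p_e − 1) · ap(w)` for every edge `e` leaving `v` on a chosen
path of any node `w`.  Boosting selects the gain argmax; the inhibiting
adaptation selects the argmin (largest expected loss).  Three readings were
fixed here:

- path probabilities are re-evaluated on the frozen path structure after
  each selection, exactly as in MPG (MoBoo is also PMIA-derived);
- the boosted edge probability is `p' = min(1, p·r)`;
- candidates are the nodes MoBoo built activation paths for — the
  already-spreading roots are excluded.  With roots eligible, every root
  dominates the gain ranking (all of its tree's paths pass through it) and
  the heuristic degenerates to "select the target seed set", which
  measurably over-boosts relative to the published behaviour of the
  heuristic and inverts its ordering against MPG.

## Synthetic networks

- **Small-world** (Kleinberg-style): nodes on a toroidal `rows × cols`
  lattice (most-square factorisation of `n`; an aspect ratio above 4 is
  rejected), 4 von Neumann lattice neighbours each, plus one long-range
  edge sourced per node with target probability ∝ `d^(−q)` (`q` the
  clustering exponent, `d` toroidal Manhattan distance); collisions are
  resampled.  Mean degree ≈ 6.
- **Scale-free** (Barabási–Albert-style): 10 initially unconnected nodes;
  each evolution step adds one node with `m` distinct edges to existing
  nodes drawn ∝ (degree + 1).  The +1 smoothing is what lets the isolated
  seed nodes acquire edges at all; duplicates are resampled.  Edge count is
  exactly `m(n − 10)`.
- **LTM attributes**: per node and concept, thresholds i.i.d.
  Normal(0.8, 0.05) clamped to [0.05, 1] (the clamp touches < 10⁻⁴ of
  draws); per concept, each incoming edge of a node weighted uniformly
  `1/in-degree` — the canonical LTM weighting; with thresholds near 0.8 an
  average node needs most of its neighbourhood active, mirroring the low
  ICM infection probability.

Graphs are undirected with endpoint-symmetric influence.  These generators
emulate the two topological regimes that dominate real social networks —
high clustering with short paths, and heavy-tailed degrees — but not their
community structure, degree assortativity or directedness.  Passing tests
therefore support conclusions about mechanism (how indirect boosting or
inhibition behaves under each regime), not calibrated predictions for any
real network; real edge lists can be loaded for exploration via the
SNAP-style reader.

## Experiment grid and statistics

One cascade is run per generated network; a cell's statistic is the mean
(and sample SD, ddof = 1) of final target activations over replicate
networks.  Per replicate `i`, RNG streams derive from `master_seed XOR i`
with separate sub-streams for generation, target seeding and each
heuristic's cascade — the grid is bit-reproducible and all heuristics in a
call see the same networks and target seeds.  Heuristic pairs are compared
with Welch's unequal-variance two-tailed t-test (the safe default when
spread heuristics produce different variances); degenerate zero-variance
pairs map to p = 1 (equal means) or p = 0.

## Numerical choices

- Strict pruning (`product > θ`) uses a relative guard of 1e−9 so that
  products that equal `θ` mathematically but land a few ulps above it in
  floating point (e.g. `0.1³` vs `10⁻³`) are excluded.
- Incrementally maintained `ap` sums are snapped to zero below 1e−15.
- LTM activation uses `Σ CI ≥ 1`; with continuous thresholds, ties have
  measure zero, but the convention is fixed.
- `max_steps` defaults to 10 000 — both models terminate at a fixed point
  long before this on any input (activation is monotone on a finite graph).
- Seeds derived for sub-streams stay below 2³¹.

## Problem sizes used in the checks

The shipped test-suite reproduces the published 25 000-node grid cells at
40 replicate networks (small-world) and 20 (scale-free); the acceptance
script uses 100 replicates for the small-world MPG/degree-discount cells
and the scale-free degree-discount cell, and 30 for MoBoo and the
scale-free MPG cells.  Statistical tolerances scale with replication
(3·SD/√n), so reduced replication widens, never narrows, the accepted
band.  Property checks (path-enumeration oracle, closed forms, orderings)
run on graphs of 3–2 500 nodes.

## Limitations

- Fixed-arborescence updates are an approximation to fresh rescoring after
  every selection (exact for the initial scores); see above.
- The LTM edge-weighting scheme is a convention (uniform 1/in-degree); no
  published weighting was available, so LTM cell values are validated as
  orderings and invariants rather than magnitudes.
- The n-concept generalisation composes pairwise effects multiplicatively;
  only the two-concept case is exercised by the experiments.
- No SIS/SIR deactivation, no multi-layer topologies, no asynchronous
  scheduling.
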