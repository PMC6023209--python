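"""Concept systems and the contextual-influence computation.

Two concepts spread simultaneously: a *target* concept ``t`` whose seeds
cannot be chosen, and a *controllable* concept ``s`` whose seeds are placed
to indirectly boost (r > 1) or inhibit (r < 1) the target's spread.  The
influence an infector exerts on a receiver for the target concept is scaled
by ``r`` once for each interaction endpoint that carries ``s``, capped at 1:

    CI = min(1, I * r**k),   k = [s on infector] + [s on receiver].

``RelationshipMatrix`` generalises this to any number of concepts with
multiplicatively composed pairwise effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

__all__ = [
    "ConceptSystem",
    "RelationshipMatrix",
    "contextual_influence",
    "influence_strength_icm",
    "influence_strength_ltm",
]

ICM = "ICM"
LTM = "LTM"


@dataclass(frozen=True)
class ConceptSystem:
    """The two-concept environment: ids, relationship strength, base rate.

    Parameters
    ----------
    target_id, controllable_id:
        Concept identifiers for the target (``t``) and controllable (``s``)
        concepts.
    r:
        Relationship strength in [0, inf).  ``r < 1`` inhibits the target,
        ``r > 1`` boosts it, ``r = 1`` is neutral.
    p:
        Base ICM transmission probability in [0, 1].
    model_tag:
        Either ``"ICM"`` or ``"LTM"``.
    """

    target_id: str = "t"
    controllable_id: str = "s"
    r: float = 1.0
    p: float = 0.1
    model_tag: str = ICM

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("relationship strength r must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("base probability p must lie in [0, 1]")
        if self.model_tag not in (ICM, LTM):
            raise ValueError(f"unknown model tag {self.model_tag!r}")
        if self.target_id == self.controllable_id:
            raise ValueError("target and controllable concepts must differ")

    @property
    def concepts(self):
        return (self.target_id, self.controllable_id)

    def relationship_matrix(self) -> "RelationshipMatrix":
        m = RelationshipMatrix()
        m.set_effect(self.controllable_id, self.target_id, self.r)
        return m


class RelationshipMatrix:
    """Pairwise multipliers ``effect[c_active][c_spreading]``, default 1.

    When concept ``c`` spreads across an edge, its base influence is
    multiplied by ``effect[a][c]`` for every concept ``a`` active on the
    infector and again for every concept active on the receiver, then capped
    at 1.  With only the (s -> t) entry set to ``r`` this reproduces the
    two-concept contextual-influence rule exactly.
    """

    def __init__(self):
        self._effect: Dict[str, Dict[str, float]] = {}

    def set_effect(self, c_active: str, c_spreading: str, value: float) -> None:
        if value < 0:
            raise ValueError("relationship multipliers must be nonnegative")
        if c_active == c_spreading and value != 1.0:
            raise ValueError("a concept cannot modify its own spread")
        self._effect.setdefault(c_active, {})[c_spreading] = float(value)

    def effect(self, c_active: str, c_spreading: str) -> float:
        if c_active == c_spreading:
            return 1.0
        return self._effect.get(c_active, {}).get(c_spreading, 1.0)

    def contextual(
        self,
        base_influence: float,
        infector_concepts: Iterable[str],
        receiver_concepts: Iterable[str],
        spreading: str,
    ) -> float:
        """Generalised contextual influence, capped at 1."""
        if not 0.0 <= base_influence <= 1.0:
            raise ValueError("base influence must lie in [0, 1]")
        value = base_influence
        for c in infector_concepts:
            value *= self.effect(c, spreading)
        for c in receiver_concepts:
            value *= self.effect(c, spreading)
        return min(1.0, value)


def contextual_influence(
    base_influence: float,
    s_on_infector: bool,
    s_on_receiver: bool,
    r: float,
) -> float:
    """Scale a base influence by r once per endpoint carrying ``s``.

    Returns ``min(1, base_influence * r**k)`` with ``k`` the number of
    interaction endpoints (infector, receiver) on which the controllable
    concept is active.  Equals the base influence when ``k = 0`` or
    ``r = 1``.
    """
    if r < 0:
        raise ValueError("relationship strength r must be nonnegative")
    if not 0.0 <= base_influence <= 1.0:
        raise ValueError("base influence must lie in [0, 1]")
    k = int(bool(s_on_infector)) + int(bool(s_on_receiver))
    if k == 0:
        return min(1.0, base_influence)
    return min(1.0, base_influence * r**k)


def influence_strength_icm(cs: ConceptSystem) -> float:
    """ICM influence strength: the base probability ``p`` on every edge."""
    return cs.p


def influence_strength_ltm(w: float, T: float) -> float:
    """LTM influence strength: ``min(1, w / T)``.

    The edge weight is expressed as the fraction of the receiver's
    threshold it satisfies, capped at 1 (a guaranteed activation).
    """
    if T <= 0:
        raise ValueError("threshold must be positive")
    if w < 0:
        raise ValueError("edge weight must be nonnegative")
    return min(1.0, w / T)
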