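"""Friend-choice algorithms that complete ego networks to a degree target.

Starting from a kin network ``g`` (adjacency ``a``), friendship edges are
added one at a time to the combined social network ``h`` (adjacency ``b``,
initially equal to ``a``) until every agent reaches the uniform degree target
ν, or no eligible unconnected pair remains. Each round:

1. the *eligible set* X collects all agents with degree < ν in ``b``;
2. the agent xi in X with the fewest contacts is selected (ties random);
3. a partner xj in X, not already connected to xi, is selected by the active
   choice rule, and the edge (xi, xj) is created.

Three choice rules are implemented:

``homophily``
    xj minimises the type distance |φ_xi − φ_xj|.
``weighted``
    xj minimises (φ_xi − φ_xj)² · d_b(xi, xj)^0.5, where d_b is the
    shortest-path length on the current combined network; pairs in different
    components use a sentinel distance (default n) and stay selectable.
``random``
    xj is uniform over the eligible, unconnected candidates.

Kin edges are never removed, so ``g`` is always a subgraph of ``h``; agents
whose kin degree already meets ν never enter X and gain no friends.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Literal, Optional

import networkx as nx
import numpy as np

from .pedigree import Agent, KinNetwork

__all__ = [
    "CostParams",
    "SocialNetwork",
    "type_distance",
    "weighted_cost",
    "eligible_set",
    "pick_min_degree",
    "pick_partner_homophily",
    "pick_partner_weighted",
    "pick_partner_random",
    "fill_friendships",
    "ALGORITHMS",
]

ALGORITHMS = ("homophily", "weighted", "random")
Algorithm = Literal["homophily", "weighted", "random"]
Tiebreak = Literal["random", "index"]


@dataclass(frozen=True)
class CostParams:
    """Exponents of the distance-weighted homophily cost.

    cost = |Δφ|^trait_exponent · d^distance_exponent. Defaults (2, 0.5) encode
    that larger trait distances are disliked with increasing intensity while
    extra graph distance matters less the further away the candidate already
    is. ``unreachable_distance`` replaces d for cross-component pairs; ``None``
    means "use n", an upper bound on any finite shortest path.
    """

    trait_exponent: float = 2.0
    distance_exponent: float = 0.5
    unreachable_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.trait_exponent > 0 and self.distance_exponent > 0):
            raise ValueError("cost exponents must be positive")
        if self.unreachable_distance is not None and not self.unreachable_distance > 0:
            raise ValueError("unreachable_distance must be positive")


@dataclass
class SocialNetwork:
    """Combined kin + friendship network with a uniform degree target.

    ``kin`` holds the immutable kin adjacency ``a``; ``full`` the combined
    adjacency ``b`` (kin edges carry ``is_kin=True``, friendship edges
    ``is_kin=False``). Both graphs share the node set ``0..n-1``.
    """

    agents: list[Agent]
    kin: nx.Graph
    full: nx.Graph
    nu: int

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError("degree target nu must be >= 1")
        n = len(self.agents)
        for g in (self.kin, self.full):
            if set(g.nodes) != set(range(n)):
                raise ValueError("graph node set must be 0..n-1")
        missing = [e for e in self.kin.edges if not self.full.has_edge(*e)]
        if missing:
            raise ValueError("kin edges must be contained in the full network")
        nx.set_edge_attributes(self.full, False, "is_kin")
        for u, v in self.kin.edges:
            self.full.edges[u, v]["is_kin"] = True

    @classmethod
    def from_kin(cls, net: KinNetwork, nu: int) -> "SocialNetwork":
        """Initialise b = a: the social network before any friend is added."""
        return cls(agents=list(net.agents), kin=net.graph.copy(),
                   full=net.graph.copy(), nu=nu)

    @property
    def n(self) -> int:
        return len(self.agents)

    def traits(self) -> np.ndarray:
        return np.array([a.trait for a in self.agents], dtype=float)

    def degree(self, i: int) -> int:
        return self.full.degree(i)

    def friend_edges(self) -> list[tuple[int, int]]:
        return [e for e, k in nx.get_edge_attributes(self.full, "is_kin").items() if not k]


def type_distance(trait_i: float, trait_j: float) -> float:
    """Absolute trait difference |φ_i − φ_j| — the homophily cost."""
    return abs(trait_i - trait_j)


def weighted_cost(
    trait_i: float,
    trait_j: float,
    graph_dist: float,
    params: CostParams = CostParams(),
) -> float:
    """Type distance weighted by graph distance.

    With default exponents: (φ_i − φ_j)² · d^0.5. ``graph_dist`` is the
    shortest-path length on the current combined network, or the unreachable
    sentinel for cross-component pairs (substituted by the caller).
    """
    return (
        abs(trait_i - trait_j) ** params.trait_exponent
        * graph_dist ** params.distance_exponent
    )


def eligible_set(net: SocialNetwork) -> set[int]:
    """X = {i : deg_b(i) < ν} — agents still seeking contacts."""
    return {i for i in range(net.n) if net.full.degree(i) < net.nu}


def _tiebreak(ids: np.ndarray, rng: np.random.Generator, tiebreak: Tiebreak) -> int:
    if tiebreak == "index" or len(ids) == 1:
        return int(ids.min())
    return int(rng.choice(ids))


def pick_min_degree(
    X: set[int],
    net: SocialNetwork,
    rng: np.random.Generator,
    tiebreak: Tiebreak = "random",
) -> int:
    """The member of X with the lowest contact count; ties broken at random."""
    if not X:
        raise ValueError("eligible set is empty")
    ids = np.fromiter(X, dtype=int)
    degs = np.array([net.full.degree(int(i)) for i in ids])
    winners = ids[degs == degs.min()]
    return _tiebreak(np.sort(winners), rng, tiebreak)


def _candidates(xi: int, X: set[int], net: SocialNetwork) -> np.ndarray:
    """Eligible partners for xi: in X, not xi, not already connected."""
    adj = set(net.full.neighbors(xi))
    return np.array(sorted(j for j in X if j != xi and j not in adj), dtype=int)


def pick_partner_homophily(
    xi: int,
    X: set[int],
    net: SocialNetwork,
    rng: np.random.Generator,
    tiebreak: Tiebreak = "random",
) -> Optional[int]:
    """Partner minimising |φ_xi − φ_j| over unconnected eligible candidates."""
    cand = _candidates(xi, X, net)
    if cand.size == 0:
        return None
    traits = net.traits()
    cost = np.abs(traits[cand] - traits[xi])
    winners = cand[cost == cost.min()]
    return _tiebreak(winners, rng, tiebreak)


def _bfs_distances(adjacency: list[set[int]], source: int, n: int) -> np.ndarray:
    """Shortest-path lengths from source; -1 marks unreachable nodes."""
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        for v in adjacency[u]:
            if dist[v] < 0:
                dist[v] = du + 1
                q.append(v)
    return dist


def pick_partner_weighted(
    xi: int,
    X: set[int],
    net: SocialNetwork,
    params: CostParams,
    rng: np.random.Generator,
    tiebreak: Tiebreak = "random",
) -> Optional[int]:
    """Partner minimising the distance-weighted cost on the current network.

    Graph distances are recomputed from xi by breadth-first search on the
    current combined adjacency (which grows as friendships are added);
    unreachable candidates use the sentinel distance and remain selectable.
    """
    cand = _candidates(xi, X, net)
    if cand.size == 0:
        return None
    adjacency = [set(net.full.neighbors(i)) for i in range(net.n)]
    dist = _bfs_distances(adjacency, xi, net.n).astype(float)
    sentinel = params.unreachable_distance if params.unreachable_distance is not None else float(net.n)
    dist[dist < 0] = sentinel
    traits = net.traits()
    cost = (
        np.abs(traits[cand] - traits[xi]) ** params.trait_exponent
        * dist[cand] ** params.distance_exponent
    )
    winners = cand[cost == cost.min()]
    return _tiebreak(winners, rng, tiebreak)


def pick_partner_random(
    xi: int,
    X: set[int],
    net: SocialNetwork,
    rng: np.random.Generator,
) -> Optional[int]:
    """Uniform draw over the unconnected eligible candidates."""
    cand = _candidates(xi, X, net)
    if cand.size == 0:
        return None
    return int(rng.choice(cand))


def fill_friendships(
    net: SocialNetwork,
    algorithm: Algorithm = "homophily",
    params: CostParams = CostParams(),
    rng: np.random.Generator | int | None = None,
    tiebreak: Tiebreak = "random",
) -> SocialNetwork:
    """Run the friend-choice loop to completion and return the filled network.

    The input network is not modified. The loop ends when every agent has ν
    contacts or when no two eligible agents remain unconnected. Because
    degrees only grow and the eligible set only shrinks, an agent that once
    found no partner never will again; such agents are set aside permanently,
    which bounds the loop by n·ν/2 edge additions plus n exhaustions.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    out = SocialNetwork(
        agents=list(net.agents), kin=net.kin.copy(), full=net.full.copy(), nu=net.nu
    )
    n, nu = out.n, out.nu
    traits = out.traits()
    adjacency: list[set[int]] = [set(out.full.neighbors(i)) for i in range(n)]
    degrees = np.array([len(adjacency[i]) for i in range(n)], dtype=int)
    eligible = degrees < nu  # X as a boolean mask
    exhausted = np.zeros(n, dtype=bool)
    sentinel = (
        params.unreachable_distance
        if params.unreachable_distance is not None
        else float(n)
    )

    max_iter = n * (nu + 1)
    added: list[tuple[int, int]] = []
    for _ in range(max_iter):
        active = eligible & ~exhausted
        if not active.any():
            break
        active_ids = np.flatnonzero(active)
        min_deg = degrees[active_ids].min()
        winners = active_ids[degrees[active_ids] == min_deg]
        xi = _tiebreak(winners, rng, tiebreak)

        cand_mask = eligible.copy()
        cand_mask[xi] = False
        for j in adjacency[xi]:
            cand_mask[j] = False
        cand = np.flatnonzero(cand_mask)
        if cand.size == 0:
            exhausted[xi] = True
            continue

        if algorithm == "random":
            xj = int(rng.choice(cand))
        else:
            if algorithm == "homophily":
                cost = np.abs(traits[cand] - traits[xi])
            else:
                dist = _bfs_distances(adjacency, xi, n).astype(float)
                dist[dist < 0] = sentinel
                cost = (
                    np.abs(traits[cand] - traits[xi]) ** params.trait_exponent
                    * dist[cand] ** params.distance_exponent
                )
            winners = cand[cost == cost.min()]
            xj = _tiebreak(winners, rng, tiebreak)

        adjacency[xi].add(xj)
        adjacency[xj].add(xi)
        degrees[xi] += 1
        degrees[xj] += 1
        if degrees[xi] >= nu:
            eligible[xi] = False
        if degrees[xj] >= nu:
            eligible[xj] = False
        added.append((xi, xj))
    else:
        raise RuntimeError(
            f"friendship loop exceeded {max_iter} iterations — bookkeeping bug"
        )

    out.full.add_edges_from(added, is_kin=False)
    return out
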