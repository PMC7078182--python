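"""Synthetic kin networks from a three-generation pedigree.

A kin network is an undirected simple graph on a cohort of *egos* whose edges
are sibling or first-cousin relations. Two egos are kin (adjacent) exactly when
they share at least two grandparents: full siblings share all four, first
cousins share the two grandparents on the side of the sibling parents.

The generator builds the minimal pedigree that realises this edge rule:

* generation 0 — founder couples;
* generation 1 — each founder couple draws a number of offspring from the
  family-size law (mean = ``fertility``); generation-1 individuals are paired
  into monogamous couples uniformly at random, excluding own siblings (sex is
  not modelled, as it plays no role in the edge rule);
* generation 2 — each generation-1 couple draws offspring; these are the egos.

Fertility (mean offspring per couple) is the single knob that drives kin
availability: higher fertility means more siblings and cousins per ego, hence
higher mean kin degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Agent",
    "PedigreeParams",
    "KinNetwork",
    "generate_pedigree",
    "assign_traits",
    "kin_degree_profile",
]

FAMILY_SIZE_LAWS = ("binomial", "poisson", "fixed")


@dataclass(frozen=True)
class Agent:
    """One ego of the simulated cohort.

    Parameters
    ----------
    id:
        0-based index within the cohort.
    trait:
        Continuous one-dimensional type φ used by homophilic friend choice;
        drawn once, uniform on [0, 100] by default, and immutable.
    grandparents:
        The four founder (generation-0) identifiers of the ego's two parental
        couples. Kinship is decided by the size of the intersection of these
        sets: ≥ 2 shared identifiers means sibling or first cousin.
    generation:
        Pedigree depth; egos are generation 2.
    """

    id: int
    trait: float
    grandparents: frozenset[int]
    generation: int = 2

    def __post_init__(self) -> None:
        if self.generation == 2 and len(self.grandparents) != 4:
            raise ValueError(
                f"generation-2 agent {self.id} must have exactly 4 grandparent "
                f"identifiers, got {len(self.grandparents)}"
            )


@dataclass(frozen=True)
class PedigreeParams:
    """Configuration of the pedigree generator.

    ``fertility`` is the mean number of offspring per couple, applied in both
    reproductive generations. ``family_size_law`` selects the offspring-count
    distribution: ``binomial`` draws Binomial(binomial_max, fertility /
    binomial_max); ``poisson`` draws Poisson(fertility); ``fixed`` uses the
    constant integer value (fertility must then be a whole number).
    """

    n_egos: int = 500
    fertility: float = 2.0
    family_size_law: str = "binomial"
    binomial_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_egos < 2:
            raise ValueError("n_egos must be at least 2")
        if not self.fertility > 0:
            raise ValueError("fertility must be positive")
        if self.family_size_law not in FAMILY_SIZE_LAWS:
            raise ValueError(
                f"family_size_law must be one of {FAMILY_SIZE_LAWS}, "
                f"got {self.family_size_law!r}"
            )
        if self.family_size_law == "binomial":
            if self.binomial_max < 1:
                raise ValueError("binomial_max must be a positive integer")
            if self.fertility > self.binomial_max:
                raise ValueError(
                    "binomial family-size law requires fertility <= binomial_max"
                )
        if self.family_size_law == "fixed" and self.fertility != int(self.fertility):
            raise ValueError("fixed family-size law requires integer fertility")


@dataclass
class KinNetwork:
    """A cohort of egos plus their sibling/first-cousin adjacency.

    The adjacency is held as an undirected simple :class:`networkx.Graph` whose
    nodes are the agent ids ``0..n-1``; it is symmetric with zero diagonal by
    construction. ``graph`` carries ``trait`` and ``generation`` node
    attributes (kept in sync with ``agents`` by :func:`assign_traits`).
    """

    agents: list[Agent]
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.agents]
        if ids != list(range(len(ids))):
            raise ValueError("agent ids must be 0..n-1 in order")
        missing = set(ids) - set(self.graph.nodes)
        if missing or self.graph.number_of_nodes() != len(ids):
            g = nx.Graph()
            g.add_nodes_from(ids)
            g.add_edges_from(self.graph.edges)
            self.graph = g
        if any(self.graph.has_edge(i, i) for i in ids):
            raise ValueError("kin adjacency must have zero diagonal")
        self._sync_node_attrs()

    def _sync_node_attrs(self) -> None:
        for a in self.agents:
            self.graph.nodes[a.id]["trait"] = a.trait
            self.graph.nodes[a.id]["generation"] = a.generation

    @property
    def n(self) -> int:
        return len(self.agents)

    def traits(self) -> np.ndarray:
        return np.array([a.trait for a in self.agents], dtype=float)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 kin adjacency matrix ``a``."""
        return nx.to_numpy_array(self.graph, nodelist=range(self.n), dtype=np.int8)

    def shared_grandparents(self, i: int, j: int) -> int:
        return len(self.agents[i].grandparents & self.agents[j].grandparents)


def _draw_offspring(rng: np.random.Generator, params: PedigreeParams, n_couples: int) -> np.ndarray:
    if params.family_size_law == "binomial":
        p = params.fertility / params.binomial_max
        return rng.binomial(params.binomial_max, p, size=n_couples)
    if params.family_size_law == "poisson":
        return rng.poisson(params.fertility, size=n_couples)
    return np.full(n_couples, int(params.fertility), dtype=int)


def _pair_generation1(
    rng: np.random.Generator, parents_of: list[int]
) -> list[tuple[int, int]]:
    """Pair generation-1 individuals into couples, excluding own siblings.

    ``parents_of[k]`` is the founder-couple index of individual ``k``. A random
    greedy matching: shuffle, then repeatedly pair the first unmatched
    individual with a random unmatched non-sibling. Individuals left without a
    feasible partner (odd counts, all-sibling residue) remain childless.
    """
    order = rng.permutation(len(parents_of))
    unmatched = list(order)
    couples: list[tuple[int, int]] = []
    while len(unmatched) >= 2:
        a = unmatched.pop(0)
        choices = [k for k in unmatched if parents_of[k] != parents_of[a]]
        if not choices:
            continue  # a stays unpaired; rest may still pair among themselves
        b = choices[rng.integers(len(choices))]
        unmatched.remove(b)
        couples.append((int(a), int(b)))
    return couples


def _edges_from_grandparents(grandparent_sets: list[frozenset[int]]) -> list[tuple[int, int]]:
    """All ego pairs sharing >= 2 grandparent identifiers.

    Grouping by individual grandparent id keeps this near-linear: a pair can
    share >= 2 ids only if it co-occurs under at least one shared id.
    """
    by_gp: dict[int, list[int]] = {}
    for ego, gps in enumerate(grandparent_sets):
        for gp in gps:
            by_gp.setdefault(gp, []).append(ego)
    candidate_pairs: set[tuple[int, int]] = set()
    for members in by_gp.values():
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                candidate_pairs.add((members[ii], members[jj]))
    return [
        (i, j)
        for i, j in candidate_pairs
        if len(grandparent_sets[i] & grandparent_sets[j]) >= 2
    ]


def generate_pedigree(params: PedigreeParams) -> KinNetwork:
    """Simulate a three-generation pedigree and return the ego kin network.

    The founder pool is sized so that the expected ego count is at least
    1.2 × ``n_egos``; if a draw still falls short the pool is enlarged
    (bounded number of retries) before the surplus cohort is uniformly
    subsampled down to exactly ``n_egos`` egos, keeping induced kin edges.
    Subsampling mimics observing a cross-section of the population and
    preserves the fertility–kin-degree link.

    Raises
    ------
    RuntimeError
        If the pedigree cannot supply ``n_egos`` egos after repeated founder
        pool enlargements (infeasible parameters, e.g. fertility ≈ 0 laws).
    """
    rng = np.random.default_rng(params.seed)
    f = params.fertility
    # expected egos per founder couple ~ f^2 / 2 (f children, paired, f children each)
    expected_per_founder = max(f * f / 2.0, 1e-9)
    n_founder_couples = max(4, math.ceil(1.2 * params.n_egos / expected_per_founder))
    # cap the initial pool; the retry loop below enlarges it if a draw falls
    # short, so genuinely infeasible laws fail in bounded time and memory
    n_founder_couples = min(n_founder_couples, 40 * params.n_egos)

    for _attempt in range(8):
        cohort = _simulate_cohort(rng, params, n_founder_couples)
        if len(cohort) >= params.n_egos:
            grandparent_sets = cohort
            break
        n_founder_couples = math.ceil(n_founder_couples * 1.6) + 1
    else:
        raise RuntimeError(
            "pedigree could not supply enough egos after repeated founder-pool "
            f"enlargements (params={params})"
        )

    keep = rng.choice(len(grandparent_sets), size=params.n_egos, replace=False)
    keep.sort()
    kept_sets = [grandparent_sets[k] for k in keep]
    agents = [
        Agent(id=i, trait=0.0, grandparents=gps) for i, gps in enumerate(kept_sets)
    ]
    g = nx.Graph()
    g.add_nodes_from(range(params.n_egos))
    g.add_edges_from(_edges_from_grandparents(kept_sets))
    return KinNetwork(agents=agents, graph=g)


def _simulate_cohort(
    rng: np.random.Generator, params: PedigreeParams, n_founder_couples: int
) -> list[frozenset[int]]:
    """One pedigree draw; returns the grandparent set of every generation-2 ego."""
    # founder couple c has individuals (2c, 2c+1)
    g1_counts = _draw_offspring(rng, params, n_founder_couples)
    g1_parents: list[int] = []  # founder-couple index per generation-1 individual
    for c, k in enumerate(g1_counts):
        g1_parents.extend([c] * int(k))
    couples = _pair_generation1(rng, g1_parents)
    if not couples:
        return []
    g2_counts = _draw_offspring(rng, params, len(couples))
    cohort: list[frozenset[int]] = []
    for (p, q), k in zip(couples, g2_counts):
        cp, cq = g1_parents[p], g1_parents[q]
        gps = frozenset({2 * cp, 2 * cp + 1, 2 * cq, 2 * cq + 1})
        cohort.extend([gps] * int(k))
    return cohort


def assign_traits(
    net: KinNetwork, low: float = 0.0, high: float = 100.0, seed: int = 0
) -> KinNetwork:
    """Draw every agent's trait φ independently uniform on [low, high].

    Returns a new :class:`KinNetwork` sharing the same adjacency; agents are
    replaced (traits are immutable once set).
    """
    if not low < high:
        raise ValueError("require low < high")
    rng = np.random.default_rng(seed)
    traits = rng.uniform(low, high, size=net.n)
    agents = [
        Agent(id=a.id, trait=float(t), grandparents=a.grandparents, generation=a.generation)
        for a, t in zip(net.agents, traits)
    ]
    out = KinNetwork(agents=agents, graph=net.graph.copy())
    return out


def kin_degree_profile(net: KinNetwork, nu: int = 60) -> dict[str, float]:
    """Summary of kin degrees: mean, min, max, fraction at or above ν.

    Used to verify the regime in which almost all agents have fewer relatives
    than their degree target before friendship filling.
    """
    degrees = np.array([net.graph.degree(i) for i in range(net.n)], dtype=float)
    return {
        "mean": float(degrees.mean()),
        "min": float(degrees.min()),
        "max": float(degrees.max()),
        "fraction_at_or_above_target": float(np.mean(degrees >= nu)),
    }
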