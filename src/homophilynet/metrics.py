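"""Summary statistics of the combined social network: λ and χ.

λ, the *friend ratio*, is the proportion of edges that are non-kin:
λ = 1 − Σa/Σb, with a the kin and b the combined adjacency matrix (symmetric
sums, so edge counts cancel the factor 2).

χ, the clustering coefficient, is reported in three variants because the
degree-target normalisation admits more than one reading:

* ``chi_nu_nsq`` — the triple sum Σ_ijk b_ij b_ik b_jk divided by n²ν(ν−1);
* ``chi_nu`` — the same numerator divided by nν(ν−1), the normalisation under
  which a ν-regular clique-covered network scores 1 (the default reported χ);
* ``chi_local`` — the standard Watts–Strogatz average local clustering
  coefficient, using each agent's realised degree (degree-< 2 agents count 0).

The ordered triple sum equals 6 × the number of (unordered) triangles; a
brute-force enumeration oracle is provided for testing that identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import networkx as nx
import numpy as np

from .friendship import SocialNetwork

__all__ = [
    "NetworkSummary",
    "friend_ratio",
    "closed_triple_sum",
    "clustering_nu",
    "clustering_local_avg",
    "triangle_oracle",
    "summarise",
]


@dataclass(frozen=True)
class NetworkSummary:
    """One network's λ and χ variants, with size and degree target."""

    lambda_friend_ratio: float
    chi_nu_nsq: float
    chi_nu: float
    chi_local: float
    n: int
    nu: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_friend_ratio <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if not 0.0 <= self.chi_local <= 1.0:
            raise ValueError("chi_local must be in [0, 1]")


def friend_ratio(net: SocialNetwork) -> float:
    """λ = 1 − (kin edge count)/(total edge count).

    Raises on an edgeless network (the ratio is undefined).
    """
    total = net.full.number_of_edges()
    if total == 0:
        raise ValueError("friend ratio undefined on an edgeless network")
    kin = net.kin.number_of_edges()
    return 1.0 - kin / total


def closed_triple_sum(graph: nx.Graph) -> int:
    """Σ_i Σ_j Σ_k b_ij b_ik b_jk over all ordered triples = 6 × triangles."""
    n = graph.number_of_nodes()
    b = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes), dtype=float)
    if n == 0:
        return 0
    return int(round(np.trace(b @ b @ b)))


def clustering_nu(
    net: SocialNetwork, denominator: Literal["n_squared", "n"] = "n"
) -> float:
    """Triple-sum clustering normalised by the degree target ν.

    ``denominator="n_squared"`` divides by n²ν(ν−1); ``"n"`` divides by
    nν(ν−1), the per-agent normalisation. Requires ν ≥ 2 (a degree-1 target
    admits no closed triads).
    """
    if net.nu < 2:
        raise ValueError("clustering with degree-target normalisation needs nu >= 2")
    num = closed_triple_sum(net.full)
    n, nu = net.n, net.nu
    denom = n * nu * (nu - 1)
    if denominator == "n_squared":
        denom *= n
    elif denominator != "n":
        raise ValueError("denominator must be 'n_squared' or 'n'")
    return num / denom


def clustering_local_avg(net: SocialNetwork | nx.Graph) -> float:
    """Average local clustering coefficient (agents of degree < 2 count 0)."""
    graph = net.full if isinstance(net, SocialNetwork) else net
    if graph.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(graph, count_zeros=True))


def triangle_oracle(net: SocialNetwork | nx.Graph, size_guard: int = 200) -> int:
    """Exact unordered triangle count by exhaustive triple enumeration.

    Deliberately naive (cubic); guarded to small networks. Exists as an
    independent check of :func:`closed_triple_sum`.
    """
    graph = net.full if isinstance(net, SocialNetwork) else net
    nodes = list(graph.nodes)
    if len(nodes) > size_guard:
        raise ValueError(f"triangle oracle guarded to n <= {size_guard}")
    count = 0
    for i, j, k in combinations(nodes, 3):
        if graph.has_edge(i, j) and graph.has_edge(i, k) and graph.has_edge(j, k):
            count += 1
    return count


def summarise(net: SocialNetwork) -> NetworkSummary:
    """Compute λ and all χ variants for one completed network."""
    return NetworkSummary(
        lambda_friend_ratio=friend_ratio(net),
        chi_nu_nsq=clustering_nu(net, "n_squared"),
        chi_nu=clustering_nu(net, "n"),
        chi_local=clustering_local_avg(net),
        n=net.n,
        nu=net.nu,
    )
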