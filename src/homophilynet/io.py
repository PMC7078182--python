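"""Import/export of networks and sweep metrics.

Kin networks travel as two-column edge-list CSV (0-based ids, one row per
undirected edge, no duplicates) or as GraphML with ``trait`` and
``generation`` vertex attributes; completed social networks add an ``is_kin``
edge attribute. Sweep metrics are appended to a flat CSV, and each exported
network gets a JSON sidecar recording algorithm, seed and cost parameters for
provenance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .friendship import CostParams, SocialNetwork
from .pedigree import Agent, KinNetwork

__all__ = [
    "write_edge_list",
    "read_kin_edge_list",
    "write_graphml",
    "write_social_graphml",
    "write_metrics_csv",
    "write_sidecar",
]

METRICS_COLUMNS = [
    "fertility", "replicate", "algorithm", "lambda",
    "chi_nu_nsq", "chi_nu", "chi_local", "n", "nu", "seed",
]


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Two-column CSV of undirected edges, each written once as (min, max)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            w.writerow([u, v])


def read_kin_edge_list(path: str | Path, n: int | None = None) -> KinNetwork:
    """Load a user-supplied kin network from a two-column edge-list CSV.

    Agents get placeholder grandparent sets (the edge rule is taken on trust
    for external networks) and zero traits; call
    :func:`homophilynet.pedigree.assign_traits` afterwards.
    """
    edges: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            u, v = int(row[0]), int(row[1])
            if u == v:
                raise ValueError(f"self-loop {u}-{v} not allowed in a kin network")
            edges.append((min(u, v), max(u, v)))
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate edges in kin edge list")
    n_nodes = n if n is not None else (max((max(e) for e in edges), default=-1) + 1)
    agents = [
        Agent(id=i, trait=0.0,
              grandparents=frozenset({4 * i, 4 * i + 1, 4 * i + 2, 4 * i + 3}))
        for i in range(n_nodes)
    ]
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    return KinNetwork(agents=agents, graph=g)


def write_graphml(net: KinNetwork, path: str | Path) -> None:
    """Kin network as GraphML with trait/generation vertex attributes."""
    g = net.graph.copy()
    nx.set_edge_attributes(g, True, "is_kin")
    nx.write_graphml(g, str(path))


def write_social_graphml(net: SocialNetwork, path: str | Path) -> None:
    """Completed network as GraphML; kin edges flagged by ``is_kin``."""
    g = net.full.copy()
    for a in net.agents:
        g.nodes[a.id]["trait"] = a.trait
        g.nodes[a.id]["generation"] = a.generation
    nx.write_graphml(g, str(path))


def write_metrics_csv(frame: pd.DataFrame, path: str | Path, append: bool = False) -> None:
    """Write (or append) sweep records in the canonical column order."""
    df = frame.loc[:, METRICS_COLUMNS]
    mode = "a" if append and Path(path).exists() else "w"
    df.to_csv(path, mode=mode, header=(mode == "w"), index=False)


def write_sidecar(
    path: str | Path,
    algorithm: str,
    seed: int,
    cost_params: CostParams,
    extra: dict | None = None,
) -> None:
    """JSON provenance sidecar for an exported network."""
    payload = {
        "algorithm": algorithm,
        "seed": seed,
        "cost_params": asdict(cost_params),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
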