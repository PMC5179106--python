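"""Metabolite-protein bipartite networks and protein-protein interaction graphs.

All graphs are simple and undirected.  The bipartite network carries a ``kind``
attribute (``metabolite`` or ``protein``) on every node; proteins linked to two or
more altered metabolites are flagged ``multi_changed`` (the class highlighted in the
source network figures).  PPI edge lists follow the String export convention of two
node columns plus a combined confidence score.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_bipartite",
    "find_hubs",
    "hub_neighborhood",
    "connected_clusters",
    "read_ppi_edges",
]


def build_bipartite(links: pd.DataFrame, changes: pd.DataFrame | None = None,
                    min_changed: int = 2) -> nx.Graph:
    """Build the metabolite-protein bipartite graph from a validated link table.

    Duplicate link rows collapse to one edge.  Metabolite nodes carry
    ``changed=True`` when present in ``changes``; protein nodes carry
    ``multi_changed=True`` when linked to >= ``min_changed`` altered metabolites.
    Raises if an identifier appears on both sides of the link table (which would
    create a within-type edge or self-loop).
    """
    graph = nx.Graph()
    if links.empty:
        return graph
    links = links.drop_duplicates(subset=["metabolite_id", "uniprot_id"])
    metabolites = set(links["metabolite_id"])
    proteins = set(links["uniprot_id"])
    shared = metabolites & proteins
    if shared:
        raise ValueError(f"identifiers on both sides of the link table: {sorted(shared)[:5]}")
    changed = set(changes["metabolite_id"]) if changes is not None and not changes.empty else set()

    for m in sorted(metabolites):
        graph.add_node(m, kind="metabolite", bipartite=0, changed=m in changed)
    for p in sorted(proteins):
        graph.add_node(p, kind="protein", bipartite=1)
    for row in links.sort_values(["metabolite_id", "uniprot_id"]).itertuples(index=False):
        graph.add_edge(row.metabolite_id, row.uniprot_id)
    for p in proteins:
        n_changed = sum(1 for m in graph.neighbors(p) if graph.nodes[m]["changed"])
        graph.nodes[p]["multi_changed"] = n_changed >= min_changed
    return graph


def find_hubs(graph: nx.Graph, min_degree: int = 10) -> list[tuple[str, int]]:
    """Nodes with degree >= ``min_degree``, sorted by degree descending then name.

    The default threshold of 10 matches the neighbor count of the core hub in the
    source analysis; there is no formal hub criterion beyond degree.
    """
    if min_degree < 1:
        raise ValueError(f"min_degree must be >= 1, got {min_degree}")
    hubs = [(n, d) for n, d in graph.degree if d >= min_degree]
    return sorted(hubs, key=lambda nd: (-nd[1], str(nd[0])))


def hub_neighborhood(graph: nx.Graph, hub: str) -> nx.Graph:
    """Induced subgraph on a hub plus its direct neighbors."""
    if hub not in graph:
        raise KeyError(f"hub node {hub!r} not in graph")
    return graph.subgraph([hub, *graph.neighbors(hub)]).copy()


def connected_clusters(graph: nx.Graph, min_size: int = 1) -> list[set[str]]:
    """Connected components with >= ``min_size`` nodes, largest first.

    Ties in size break lexicographically on the sorted node list, so the output
    order is deterministic.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    comps = [set(c) for c in nx.connected_components(graph) if len(c) >= min_size]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def read_ppi_edges(path: str | Path, min_score: float | None = None,
                   delimiter: str = "\t") -> nx.Graph:
    """Read a String-style PPI edge list: two protein columns plus a combined score.

    Scores above 1 are assumed to be on String's 0-1000 scale and divided by 1000.
    ``min_score`` (on the 0-1 scale) filters edges; no default cutoff is claimed.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected at least two node columns, got {cols}")
    a_col, b_col = cols[0], cols[1]
    score_col = cols[2] if len(cols) > 2 else None
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = getattr(row, a_col), getattr(row, b_col)
        if a == b:
            continue
        weight = None
        if score_col is not None:
            weight = float(getattr(row, score_col))
            if weight > 1:
                weight = weight / 1000.0
            if not 0 <= weight <= 1:
                raise ValueError(f"{path}: confidence weight {weight} outside [0, 1]")
            if min_score is not None and weight < min_score:
                continue
        if weight is None:
            graph.add_edge(a, b)
        else:
            graph.add_edge(a, b, weight=weight)
    return graph
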