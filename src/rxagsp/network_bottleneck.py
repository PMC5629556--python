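"""Disease-network construction and betweenness bottleneck ranking.

Edges combine protein-protein interactions and regulator->target links
into one simple undirected graph (edge type kept as metadata).  Bottleneck
nodes are those with the highest exact shortest-path betweenness
(unnormalised, endpoints excluded); ties are broken alphabetically so the
ranking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["NodeScore", "build_graph", "betweenness_rank", "induce_subnetwork"]

log = logging.getLogger(__name__)


@dataclass
class NodeScore:
    node: str
    betweenness: float
    rank: int


def build_graph(
    edge_table: pd.DataFrame, node_annotations: pd.DataFrame | None = None
) -> nx.Graph:
    """Build a simple undirected graph from an edge table.

    ``edge_table`` needs columns node_a, node_b, edge_type; self-loops are
    dropped (count logged) and duplicate edges collapse to one.  Optional
    ``node_annotations`` (column ``gene_id`` plus arbitrary attribute
    columns) are joined onto the nodes by symbol.
    """
    g = nx.Graph()
    n_loops = 0
    for row in edge_table.itertuples(index=False):
        a, b = str(row.node_a), str(row.node_b)
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b, edge_type=getattr(row, "edge_type", "ppi"))
    if n_loops:
        log.info("dropped %d self-loop edges", n_loops)
    if node_annotations is not None:
        ann = node_annotations.set_index("gene_id")
        for node in g.nodes:
            if node in ann.index:
                g.nodes[node].update(ann.loc[node].to_dict())
    return g


def betweenness_rank(graph: nx.Graph, top_k: int | None = None) -> list[NodeScore]:
    """Rank nodes by exact unnormalised shortest-path betweenness.

    Disconnected graphs are fine (cross-component pairs contribute 0).
    Descending betweenness, alphabetical within ties; the top ``top_k``
    scores are returned (all nodes when top_k is None).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    bc = nx.betweenness_centrality(graph, normalized=False, endpoints=False)
    ordered = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    scores = [
        NodeScore(node=node, betweenness=float(val), rank=i + 1)
        for i, (node, val) in enumerate(ordered)
    ]
    return scores[:top_k] if top_k is not None else scores


def induce_subnetwork(
    graph: nx.Graph, seed_nodes, include_neighbors: bool = False
) -> nx.Graph:
    """Vertex-induced subgraph on seed nodes (optionally plus neighbors).

    Seed nodes absent from the graph are logged and skipped; attributes are
    preserved.  An empty seed list yields an empty graph.
    """
    seeds = [str(s) for s in seed_nodes]
    missing = [s for s in seeds if s not in graph]
    if missing:
        log.info("ignoring %d seed nodes absent from the graph", len(missing))
    present = [s for s in seeds if s in graph]
    keep = set(present)
    if include_neighbors:
        for s in present:
            keep.update(graph.neighbors(s))
    return graph.subgraph(keep).copy()


def scores_table(scores: list[NodeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"node": s.node, "betweenness": s.betweenness, "rank": s.rank} for s in scores]
    )
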