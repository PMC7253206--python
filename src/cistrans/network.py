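"""Coexpression-network neighborhoods, betweenness, and TF enrichment.

Consumes a precomputed mutual-information (MI) edge list with a transcription
factor flag per node. First-neighbor subnetworks around candidate genes,
shortest-path betweenness centrality (a hubness/pleiotropy proxy), and a
one-sided hypergeometric test for TF enrichment in a neighborhood against
the whole-network background.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cistrans")


def load_network(edge_path, node_path=None) -> nx.Graph:
    """Graph from an edge TSV (node1, node2, mi) and optional node annotations.

    Node annotations (node, is_tf, log2fc) become node attributes; self-loops
    and nonpositive MI weights are rejected.
    """
    edges = pd.read_csv(edge_path, sep="\t")
    net = nx.Graph()
    for n1, n2, mi in edges.itertuples(index=False):
        if n1 == n2:
            raise ValueError(f"self-loop on node {n1!r}")
        if mi <= 0:
            raise ValueError(f"nonpositive MI weight on edge {n1!r}-{n2!r}")
        net.add_edge(n1, n2, mi=float(mi))
    if node_path is not None:
        nodes = pd.read_csv(node_path, sep="\t").set_index("node")
        for node, row in nodes.iterrows():
            if node in net:
                net.nodes[node]["is_tf"] = bool(row.get("is_tf", False))
                if "log2fc" in row and pd.notna(row["log2fc"]):
                    net.nodes[node]["log2fc"] = float(row["log2fc"])
        for node in net.nodes:
            net.nodes[node].setdefault("is_tf", False)
    return net


def first_neighbors(
    net: nx.Graph, node, mi_threshold: float | None = None
) -> nx.Graph:
    """Induced subgraph on a node and its direct neighbors, weights preserved.

    ``mi_threshold`` restricts the neighborhood to edges from the center with
    MI at or above the threshold before inducing the subgraph.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not present in the network")
    neighbors = {
        nb for nb in net.neighbors(node)
        if mi_threshold is None or net.edges[node, nb]["mi"] >= mi_threshold
    }
    return net.subgraph(neighbors | {node}).copy()


def betweenness(net: nx.Graph, weighted: bool = False) -> dict:
    """Shortest-path betweenness, computed and normalized per component.

    Paths are unweighted hops by default (MI reflects coexpression strength,
    not path cost); ``weighted=True`` uses 1/MI as the edge length so high-MI
    edges are short. Normalization divides by (n-1)(n-2)/2 with n the size
    of the node's connected component.
    """
    if weighted:
        for u, v, data in net.edges(data=True):
            data["_len"] = 1.0 / data["mi"]
    result: dict = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        result.update(
            nx.betweenness_centrality(
                sub, normalized=True, weight="_len" if weighted else None
            )
        )
    return result


def tf_enrichment(net: nx.Graph, subnetwork_nodes) -> float:
    """One-sided hypergeometric upper-tail p for TF overrepresentation.

    The urn is the whole network (N nodes, K of them TFs); the draw is the
    subnetwork (n nodes, k TFs); p = P(X >= k).
    """
    sub = set(subnetwork_nodes)
    if not sub:
        raise ValueError("subnetwork must be nonempty")
    missing = sub - set(net.nodes)
    if missing:
        raise ValueError(f"subnetwork nodes absent from network: {sorted(missing)}")
    N = net.number_of_nodes()
    K = sum(1 for n in net.nodes if net.nodes[n].get("is_tf", False))
    n = len(sub)
    k = sum(1 for node in sub if net.nodes[node].get("is_tf", False))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def write_subnetwork(net: nx.Graph, path) -> None:
    """Export an edge list TSV (node1, node2, mi) for graph viewers."""
    rows = [(u, v, d["mi"]) for u, v, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["node1", "node2", "mi"]).to_csv(
        path, sep="\t", index=False
    )
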