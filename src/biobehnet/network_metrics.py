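"""Descriptive graph statistics for the regulatory network.

Global statistics (connection density, average clustering) and per-node
centralities (in/out degree, closeness, betweenness, mean out-going shortest
path length), matching the conventions of standard network-analysis tools:
clustering on the undirected projection, betweenness on the directed graph
normalized by (N-1)(N-2) with endpoints excluded, and closeness with the
Wasserman-Faust correction for incomplete reachability.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network_io import Network, NetworkError


def connection_density(net: Network) -> float:
    """Edges as a fraction of all possible directed edges, E / (N*(N-1))."""
    n = len(net.nodes)
    if n < 2:
        raise NetworkError("density needs at least 2 nodes")
    return len(net.edges) / (n * (n - 1))


def clustering_coefficient(net: Network, directed: bool = False) -> float:
    """Average local clustering coefficient.

    By default the graph is projected to an undirected simple graph (the
    convention of common GUI network tools); ``directed=True`` uses the
    directed generalization instead.  Nodes of degree < 2 contribute 0.
    """
    g = net.to_networkx()
    if len(g) < 3:
        raise NetworkError("clustering needs at least 3 nodes")
    if not directed:
        g = g.to_undirected()
    return float(nx.average_clustering(g, count_zeros=True))


def centralities(net: Network) -> pd.DataFrame:
    """Per-node centrality table.

    Columns: ``indegree``, ``outdegree``, ``closeness`` (out-going distances,
    Wasserman-Faust reachability correction), ``betweenness`` (directed,
    normalized, endpoints excluded), ``avg_shortest_path_out`` (mean hops to
    the nodes reachable from the node; NaN when nothing is reachable).
    """
    g = net.to_networkx()
    n = len(g)
    indeg = dict(g.in_degree())
    outdeg = dict(g.out_degree())
    # closeness on outgoing distances == standard (incoming) closeness of the
    # reversed graph
    clo = nx.closeness_centrality(g.reverse(), wf_improved=True)
    btw = nx.betweenness_centrality(g, normalized=True, endpoints=False)
    avg_out = {}
    for u in g.nodes:
        dist = nx.single_source_shortest_path_length(g, u)
        dist.pop(u, None)
        avg_out[u] = float(np.mean(list(dist.values()))) if dist else float("nan")
    ids = sorted(g.nodes)
    df = pd.DataFrame({
        "indegree": [indeg[i] for i in ids],
        "outdegree": [outdeg[i] for i in ids],
        "closeness": [clo[i] for i in ids],
        "betweenness": [btw[i] for i in ids],
        "avg_shortest_path_out": [avg_out[i] for i in ids],
    }, index=pd.Index(ids, name="node"))
    assert df["indegree"].sum() == len(net.edges)
    assert df["outdegree"].sum() == len(net.edges)
    return df


def global_stats(net: Network) -> dict:
    """One-line global summary used by the `describe` command."""
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "density": connection_density(net),
        "clustering_coefficient": clustering_coefficient(net),
    }
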