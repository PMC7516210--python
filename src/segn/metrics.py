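"""Node-centrality features of reconstructed networks.

Six per-node features characterize a snapshot: connectivity (degree),
closeness, betweenness, eccentricity, eigenvector centrality, and
PageRank.  All but PageRank are computed on the undirected skeleton;
PageRank uses the directed graph with damping 0.85.  On disconnected
graphs, closeness and eccentricity are computed within components and the
report is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .taxonomy import SignedNetwork

__all__ = ["CentralityReport", "centrality_suite"]

METRIC_COLUMNS = [
    "connectivity", "closeness", "betweenness", "eccentricity",
    "eigenvector", "pagerank",
]


@dataclass
class CentralityReport:
    per_node: pd.DataFrame          # index node, columns METRIC_COLUMNS
    disconnected: bool

    def averages(self, nodes=None) -> pd.Series:
        sub = self.per_node if nodes is None else self.per_node.loc[list(nodes)]
        return sub.mean(axis=0)


def centrality_suite(network: SignedNetwork | nx.DiGraph, nodes=None) -> CentralityReport:
    """Standard centrality definitions on a network snapshot.

    Closeness is the normalized (n-1)/sum-of-distances form; betweenness is
    the raw shortest-path count (unnormalized); eigenvector centrality is
    the principal adjacency eigenvector.  ``nodes`` restricts the report
    rows, not the underlying graph.
    """
    g = network.graph if isinstance(network, SignedNetwork) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    ug = g.to_undirected()

    degree = dict(ug.degree())
    betweenness = nx.betweenness_centrality(ug, normalized=False)
    # link structure only: signed edge weights would corrupt the
    # stochastic transition matrix
    pagerank = nx.pagerank(g, alpha=0.85, weight=None)
    try:
        eigenvector = nx.eigenvector_centrality_numpy(ug)
    except Exception:
        eigenvector = {n: 0.0 for n in ug}

    closeness, eccentricity = {}, {}
    components = list(nx.connected_components(ug))
    for comp in components:
        sub = ug.subgraph(comp)
        ecc = nx.eccentricity(sub) if len(comp) > 1 else {next(iter(comp)): 0}
        eccentricity.update(ecc)
        for u in comp:
            if len(comp) == 1:
                closeness[u] = 0.0
            else:
                total = sum(nx.single_source_shortest_path_length(sub, u).values())
                closeness[u] = (len(comp) - 1) / total
    disconnected = len(components) > 1

    frame = pd.DataFrame({
        "connectivity": degree,
        "closeness": closeness,
        "betweenness": betweenness,
        "eccentricity": eccentricity,
        "eigenvector": eigenvector,
        "pagerank": pagerank,
    })[METRIC_COLUMNS]
    if nodes is not None:
        frame = frame.loc[list(nodes)]
    return CentralityReport(per_node=frame.sort_index(), disconnected=disconnected)
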