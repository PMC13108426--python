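"""Protein-interaction network topology for candidate gene sets.

The node set is supplied independently of the edge list so that genes
with no retained interaction still count towards density and average
degree (highly disconnected networks are the norm for small candidate
sets).  Edges below the confidence score threshold are dropped; the
remaining graph is simple and undirected.  Closeness uses the harmonic
variant (defined on disconnected graphs); eigenvector centrality is
computed per connected component; hubs are nodes whose degree exceeds
mean(degree) + SD(degree).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class NetworkMetrics:
    def __init__(self, per_node: pd.DataFrame, density: float, average_degree: float, hubs: list, graph: nx.Graph):
        self.per_node = per_node
        self.density = density
        self.average_degree = average_degree
        self.hubs = hubs
        self.graph = graph


def network_metrics(edges: pd.DataFrame, nodes: set, score_min: int = 400) -> NetworkMetrics:
    """Topology metrics of the thresholded interaction graph on ``nodes``.

    ``edges`` needs columns gene_a, gene_b, combined_score (0-1000 scale).
    Self-loops are dropped with a warning; duplicate edges collapse.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))  # stable order -> reproducible centralities
    n_self = 0
    for _, e in edges.iterrows():
        if e["combined_score"] < score_min:
            continue
        a, b = e["gene_a"], e["gene_b"]
        if a == b:
            n_self += 1
            continue
        if a in nodes and b in nodes:
            g.add_edge(a, b, weight=float(e["combined_score"]))
    if n_self:
        log.warning("dropped %d self-loops", n_self)

    n = g.number_of_nodes()
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * m / n if n else 0.0

    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.harmonic_centrality(g)
    eigenvector = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            eigenvector[next(iter(comp))] = 0.0
            continue
        members = sorted(comp)
        a = nx.to_numpy_array(g, nodelist=members, weight=None)
        w, v = np.linalg.eigh(a)  # deterministic principal eigenvector
        vec = v[:, -1]
        vec = np.abs(vec) / np.linalg.norm(vec)
        eigenvector.update(dict(zip(members, vec)))

    deg = np.array([degree[v] for v in g.nodes()])
    hub_cut = deg.mean() + deg.std(ddof=0)
    hubs = sorted([v for v in g.nodes() if degree[v] > hub_cut])

    per_node = pd.DataFrame(
        {
            "gene": list(g.nodes()),
            "degree": [degree[v] for v in g.nodes()],
            "betweenness": [betweenness[v] for v in g.nodes()],
            "closeness_harmonic": [closeness[v] for v in g.nodes()],
            "eigenvector": [eigenvector[v] for v in g.nodes()],
        }
    ).sort_values("gene", kind="mergesort").reset_index(drop=True)
    return NetworkMetrics(per_node, density, avg_degree, hubs, g)
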