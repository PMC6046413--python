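"""Genus co-occurrence networks and their node-level / global indexes.

Two genera are linked when they are detected together in at least one
individual carrier; the edge weight counts the carriers in which the pair
co-occurs.  One network is built per carrier x biotope stratum.  Node
indexes: weighted degree (WD), betweenness centrality (BNC, unweighted
shortest paths, unnormalized), local clustering coefficient (CC, on the
binarized graph), PageRank (PR, damping 0.85), plus Louvain modularity
communities and a Clauset–Shalizi–Newman power-law fit of the WD
distribution (the scale-free diagnostic).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd


@dataclasses.dataclass
class CooccurrenceNetwork:
    """Weighted undirected genus graph for one stratum, with node metrics."""

    graph: nx.Graph
    stratum: tuple[str | None, str | None] = (None, None)
    node_metrics: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, a: str, b: str) -> int:
        return self.graph[a][b]["weight"] if self.graph.has_edge(a, b) else 0


@dataclasses.dataclass
class PowerLawFit:
    """Continuous power-law MLE with KS-selected xmin."""

    gamma: float
    xmin: float
    ks_distance: float
    n_tail: int
    loglog_slope: float
    degenerate: bool = False


def build_network(
    presence: pd.DataFrame, stratum: tuple[str | None, str | None] = (None, None)
) -> CooccurrenceNetwork:
    """Build the co-occurrence graph from a boolean samples x taxa matrix.

    Edge (a, b) exists iff a and b are both detected in >= 1 sample; the
    weight is the number of such samples.  Taxa detected in the stratum but
    never jointly with another taxon are kept as isolated nodes; taxa never
    detected are excluded.
    """
    if presence.shape[0] == 0:
        raise ValueError("empty stratum: no samples")
    P = presence.to_numpy(dtype=np.int64)
    taxa = list(presence.columns)
    co = P.T @ P  # co-occurrence counts; diagonal = occurrence counts
    occ = np.diag(co)
    G = nx.Graph()
    for i, t in enumerate(taxa):
        if occ[i] > 0:
            G.add_node(t)
    idx = np.argwhere(np.triu(co, k=1) > 0)
    for i, j in idx:
        G.add_edge(taxa[i], taxa[j], weight=int(co[i, j]))
    return CooccurrenceNetwork(G, stratum)


def weighted_degree(net: CooccurrenceNetwork) -> dict[str, float]:
    """WD(v) = sum of weights of edges incident to v (0 for isolated nodes)."""
    return {v: float(d) for v, d in net.graph.degree(weight="weight")}


def betweenness(
    net: CooccurrenceNetwork, weighted: bool = False, normalized: bool = False
) -> dict[str, float]:
    """Exact betweenness centrality (Brandes).

    Default is the topological variant: unweighted shortest paths,
    unnormalized pair counts.  ``weighted=True`` uses 1/weight as the edge
    length so heavier co-occurrence means shorter distance.
    """
    G = net.graph
    if weighted:
        G = G.copy()
        for u, v, d in G.edges(data=True):
            d["dist"] = 1.0 / d["weight"]
        return nx.betweenness_centrality(G, weight="dist", normalized=normalized)
    return nx.betweenness_centrality(G, weight=None, normalized=normalized)


def clustering_coefficient(net: CooccurrenceNetwork) -> dict[str, float]:
    """Local clustering coefficient on the binarized graph; degree<2 -> 0."""
    return {v: float(c) for v, c in nx.clustering(net.graph).items()}


def pagerank(
    net: CooccurrenceNetwork,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> dict[str, float]:
    """PageRank by power iteration on the weight-proportional random walk.

    Isolated nodes hold teleport-only mass during iteration (their dropped
    walk mass is restored by a final renormalisation, so the returned values
    sum to 1).
    """
    nodes = list(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    index = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in net.graph.edges(data=True):
        W[index[u], index[v]] = d["weight"]
        W[index[v], index[u]] = d["weight"]
    strength = W.sum(axis=1)
    M = np.divide(W, strength[:, None], out=np.zeros_like(W), where=strength[:, None] > 0)
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        x_new = teleport + damping * (M.T @ x)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")
    x = x / x.sum()
    return {v: float(x[index[v]]) for v in nodes}


def detect_communities(
    net: CooccurrenceNetwork, resolution: float = 1.0, seed: int = 0, method: str = "louvain"
) -> dict[str, int]:
    """Modularity-maximizing partition of the genus graph.

    Louvain on edge weights by default (greedy CNM agglomeration as the
    alternative).  Labels are 0..k-1 in order of decreasing community size,
    ties broken by the lowest member label, so output is deterministic under
    a fixed seed.
    """
    G = net.graph
    if G.number_of_nodes() == 0:
        return {}
    if method == "louvain":
        comms = nx.community.louvain_communities(G, weight="weight", resolution=resolution, seed=seed)
    elif method == "cnm":
        if G.number_of_edges() == 0:
            comms = [{v} for v in G.nodes]
        else:
            comms = nx.community.greedy_modularity_communities(G, weight="weight", resolution=resolution)
    else:
        raise ValueError(f"unknown method {method!r}")
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    return {v: label for label, members in enumerate(comms) for v in members}


def modularity(net: CooccurrenceNetwork, labels: Mapping[str, int]) -> float:
    """Newman's weighted modularity Q of a partition."""
    groups: dict[int, set[str]] = {}
    for v, lab in labels.items():
        groups.setdefault(lab, set()).add(v)
    return nx.community.modularity(net.graph, list(groups.values()), weight="weight")


def fit_power_law(
    wd_values, max_xmin_candidates: int = 200, min_tail: int = 10
) -> PowerLawFit:
    """Fit a continuous power law p(x) ~ x^-gamma to positive values.

    Clauset–Shalizi–Newman procedure: for each candidate xmin the tail MLE is
    gamma = 1 + n / sum(log(x / xmin)); xmin is chosen to minimise the KS
    distance between the tail empirical CDF and the fitted CDF.  Candidate
    xmins are at most ``max_xmin_candidates`` quantile-spaced unique values.
    If no candidate leaves ``min_tail`` tail points, a warning is issued and
    the fit uses xmin = min(x).  A log-log rank regression slope is reported
    alongside for comparability.
    """
    x = np.asarray([v for v in wd_values if v > 0], dtype=float)
    if x.size < min_tail:
        raise ValueError(f"need >= {min_tail} positive values, got {x.size}")
    x = np.sort(x)
    if x[0] == x[-1]:
        return PowerLawFit(np.nan, float(x[0]), np.nan, int(x.size), np.nan, degenerate=True)

    uniq = np.unique(x)
    candidates = uniq[:-min_tail + 1] if uniq.size > min_tail else uniq[:1]
    if candidates.size > max_xmin_candidates:
        pick = np.unique(np.linspace(0, candidates.size - 1, max_xmin_candidates).astype(int))
        candidates = candidates[pick]

    best = None
    for xmin in candidates:
        tail = x[x >= xmin]
        n = tail.size
        if n < min_tail:
            continue
        logsum = np.sum(np.log(tail / xmin))
        if logsum <= 0:
            continue
        gamma = 1.0 + n / logsum
        emp = np.arange(1, n + 1) / n
        theor = 1.0 - (tail / xmin) ** (1.0 - gamma)
        ks = float(np.max(np.abs(emp - theor)))
        if best is None or ks < best[0]:
            best = (ks, gamma, float(xmin), n)
    if best is None:
        warnings.warn("fewer than min_tail points above every candidate xmin; fitting full data")
        xmin = float(x[0])
        tail = x
        gamma = 1.0 + tail.size / np.sum(np.log(tail / xmin))
        emp = np.arange(1, tail.size + 1) / tail.size
        theor = 1.0 - (tail / xmin) ** (1.0 - gamma)
        best = (float(np.max(np.abs(emp - theor))), gamma, xmin, tail.size)

    # complementary-CDF log-log regression slope (classic descriptive check)
    ccdf = 1.0 - np.arange(x.size) / x.size
    slope = float(np.polyfit(np.log(x), np.log(ccdf), 1)[0])
    ks, gamma, xmin, n_tail = best
    return PowerLawFit(gamma=float(gamma), xmin=xmin, ks_distance=ks, n_tail=n_tail, loglog_slope=slope)


def annotate(
    net: CooccurrenceNetwork,
    damping: float = 0.85,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute WD/BNC/CC/PR/community for every node and attach the table."""
    wd = weighted_degree(net)
    bnc = betweenness(net)
    cc = clustering_coefficient(net)
    pr = pagerank(net, damping=damping)
    comm = detect_communities(net, resolution=resolution, seed=seed)
    table = pd.DataFrame(
        {
            "WD": pd.Series(wd),
            "BNC": pd.Series(bnc),
            "CC": pd.Series(cc),
            "PR": pd.Series(pr),
            "community": pd.Series(comm),
        }
    ).loc[net.nodes]
    table.index.name = "genus"
    net.node_metrics = table
    for v in net.nodes:
        net.graph.nodes[v].update(table.loc[v].to_dict())
    return table


def export_graph(net: CooccurrenceNetwork, path) -> None:
    """Write the annotated graph as GEXF or GraphML (by file extension)."""
    path = str(path)
    if path.endswith(".gexf"):
        nx.write_gexf(net.graph, path)
    elif path.endswith(".graphml"):
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError("export format must be .gexf or .graphml")
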