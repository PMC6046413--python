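"""Individual-carrier similarity networks (ticks and voles as nodes).

Within one biotope, every pair of individuals — tick-tick, vole-vole or
tick-vole — is linked by the number of bacterial genera they share; Louvain
communities on the joint graph reveal whether ticks and voles mix or split.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import pandas as pd

from . import taxon_network


@dataclasses.dataclass
class CarrierNetwork:
    """Weighted graph over individual samples; node attr ``carrier``."""

    graph: nx.Graph
    biotope: str | None = None
    communities: dict[str, int] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def carrier_of(self, sample_id: str) -> str:
        return self.graph.nodes[sample_id]["carrier"]


def build_carrier_network(
    presence: pd.DataFrame,
    carriers: pd.Series,
    biotope: str | None = None,
    min_shared: int = 1,
) -> CarrierNetwork:
    """Link samples by their number of shared present genera.

    ``presence`` is the boolean samples x taxa matrix of one biotope and
    ``carriers`` maps each sample_id to its carrier.  Pairs sharing fewer
    than ``min_shared`` genera get no edge.  Samples with no detected genus
    remain isolated nodes.
    """
    if presence.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    P = presence.to_numpy(dtype="int64")
    shared = P @ P.T
    ids = list(presence.index)
    G = nx.Graph()
    for sid in ids:
        G.add_node(sid, carrier=str(carriers[sid]))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if shared[i, j] >= min_shared:
                G.add_edge(ids[i], ids[j], weight=int(shared[i, j]))
    return CarrierNetwork(G, biotope)


def detect_carrier_communities(net: CarrierNetwork, seed: int = 0, resolution: float = 1.0) -> dict[str, int]:
    """Louvain modularity communities on the joint tick+vole graph.

    Same contract as the genus-network community detection: weighted
    Louvain, labels ordered by decreasing community size, deterministic
    under a fixed seed.  The partition is stored on the network.
    """
    labels = taxon_network.detect_communities(
        taxon_network.CooccurrenceNetwork(net.graph), resolution=resolution, seed=seed
    )
    net.communities = labels
    for sid, lab in labels.items():
        net.graph.nodes[sid]["community"] = lab
    return labels


def export_graph(net: CarrierNetwork, path) -> None:
    path = str(path)
    if path.endswith(".gexf"):
        nx.write_gexf(net.graph, path)
    elif path.endswith(".graphml"):
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError("export format must be .gexf or .graphml")
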