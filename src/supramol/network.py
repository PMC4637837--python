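"""Modelable sub-networks: single-linkage clustering of templated interactions.

The interaction graph is restricted to edges that possess a structural
template (an element); its connected components are the sub-networks that
can be rendered into complex models.  Node degree (number of distinct
interaction partners within the sub-network) drives anchor selection
during assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx

from .elements import PPIElement

__all__ = ["SubNetwork", "cluster_subnetworks", "degree_of", "subnetwork_to_json"]


@dataclass
class SubNetwork:
    net_id: str
    nodes: Set[str]
    edges: List[Tuple[Tuple[str, str], PPIElement]]  # (unordered pair, element)
    degree: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.degree:
            neigh: Dict[str, Set[str]] = {n: set() for n in self.nodes}
            for (a, b), _ in self.edges:
                neigh[a].add(b)
                neigh[b].add(a)
                if a == b:
                    neigh[a].add(a)  # self-loop names one partner
            self.degree = {n: len(s) for n, s in neigh.items()}

    @property
    def size(self) -> int:
        return len(self.nodes)

    def elements_incident(self, accession: str) -> List[PPIElement]:
        return [e for (a, b), e in self.edges if accession in (a, b)]


def cluster_subnetworks(elements: Sequence[PPIElement]) -> List[SubNetwork]:
    """Connected components of the element-bearing interaction graph.

    Components are ordered by size descending, then by lexicographically
    smallest member accession, and numbered accordingly.
    """
    graph = nx.Graph()
    by_pair: Dict[Tuple[str, str], PPIElement] = {}
    for elem in elements:
        pair = elem.interaction.pair
        graph.add_edge(*pair)
        by_pair.setdefault(pair, elem)
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    nets = []
    for i, comp in enumerate(comps):
        edges = sorted(
            ((pair, elem) for pair, elem in by_pair.items()
             if pair[0] in comp or pair[1] in comp),
            key=lambda pe: pe[0],
        )
        nets.append(SubNetwork(net_id=f"SN{i + 1:03d}", nodes=comp, edges=edges))
    return nets


def degree_of(net: SubNetwork, node: str) -> int:
    """Number of distinct interaction partners of `node` in the sub-network."""
    if node not in net.nodes:
        raise KeyError(f"{node} not in sub-network {net.net_id}")
    return net.degree[node]


def subnetwork_to_json(nets: Sequence[SubNetwork]) -> str:
    doc = []
    for net in nets:
        doc.append({
            "net_id": net.net_id,
            "nodes": sorted(net.nodes),
            "degree": dict(sorted(net.degree.items())),
            "edges": [
                {"pair": list(pair), "template_entry": elem.template_entry,
                 "chain_a": elem.chain_a.chain_id, "chain_b": elem.chain_b.chain_id}
                for pair, elem in net.edges
            ],
        })
    return json.dumps(doc, indent=1, sort_keys=True)


def subnetworks_to_tsv(nets: Sequence[SubNetwork]) -> str:
    lines = ["net_id\tacc_a\tacc_b\ttemplate_entry"]
    for net in nets:
        for (a, b), elem in net.edges:
            lines.append(f"{net.net_id}\t{a}\t{b}\t{elem.template_entry}")
    return "\n".join(lines) + "\n"
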