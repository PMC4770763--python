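"""Merging significant subpathways into one global regulatory network.

Subpathways from different pathways often share miRNAs and crosstalking
genes; merging their member edges into a single graph exposes hub miRNAs
that disturb several subpathways at once. Node weights record regulatory
degree (for a miRNA, the number of distinct linked genes; for a gene, the
number of distinct linked miRNAs) and edge weights record in how many
subpathways the two endpoints co-occur, with the contributing subpathway
ids kept as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .pathway_io import DifferentialSet
from .rmpg import GENE, MIRNA, RMPG
from .subpathway import Subpathway


@dataclass
class RegulatoryNetwork:
    """Merged miRNA-gene network with provenance-weighted edges.

    Node attributes: ``kind`` (gene/mirna), ``differential`` (bool),
    ``weight`` (regulatory degree as defined above). Edge attributes:
    ``weight`` (number of distinct contributing subpathways) and
    ``subpathways`` (their ids, a frozenset equal in size to the weight).
    """

    graph: nx.Graph

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d["kind"] == MIRNA)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d["kind"] == GENE)


def merge_network(
    subpathways: Sequence[Subpathway],
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
) -> RegulatoryNetwork:
    """Union the member edges of the given subpathways into one network.

    Only edges already present in member subpathways are merged — nothing
    new is inferred — and compound labels are dropped in the network view.
    The result is independent of the order of the subpathway list.
    """
    graph = nx.Graph()
    for sp in sorted(subpathways, key=lambda s: s.subpathway_id):
        rmpg = rmpgs.get(sp.pathway_id)
        if rmpg is None:
            raise KeyError(f"subpathway {sp.subpathway_id} references unknown pathway {sp.pathway_id}")
        for node in sp.member_nodes:
            kind = rmpg.node_kind(node)
            if node not in graph:
                graph.add_node(node, kind=kind, differential=node in diff.molecules)
        for a, b in sp.member_edges:
            if graph.has_edge(a, b):
                graph.edges[a, b]["subpathways"].add(sp.subpathway_id)
            else:
                graph.add_edge(a, b, subpathways={sp.subpathway_id})
    for a, b, d in graph.edges(data=True):
        d["subpathways"] = frozenset(d["subpathways"])
        d["weight"] = len(d["subpathways"])
    for node, d in graph.nodes(data=True):
        other = GENE if d["kind"] == MIRNA else MIRNA
        d["weight"] = sum(1 for nb in graph.neighbors(node) if graph.nodes[nb]["kind"] == other)
    return RegulatoryNetwork(graph=graph)


def hub_mirnas(net: RegulatoryNetwork, top: int) -> list[tuple[str, int, int]]:
    """Top miRNAs by distinct-target count.

    Returns (miRNA id, distinct target count, distinct subpathway count)
    sorted by target count descending, ties by subpathway count descending
    then id ascending.
    """
    if top < 1:
        raise ValueError("top must be positive")
    rows = []
    for m in net.mirnas:
        targets = sum(1 for nb in net.graph.neighbors(m) if net.graph.nodes[nb]["kind"] == GENE)
        sps: set[str] = set()
        for nb in net.graph.neighbors(m):
            sps |= net.graph.edges[m, nb]["subpathways"]
        rows.append((m, targets, len(sps)))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows[:top]


def write_network(net: RegulatoryNetwork, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Export edge and node tables for external viewers."""
    erows = [
        (a, b, d["weight"], ";".join(sorted(d["subpathways"])))
        for a, b, d in sorted(
            ((min(a, b), max(a, b), d) for a, b, d in net.graph.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        )
    ]
    pd.DataFrame(erows, columns=["node_a", "node_b", "weight", "subpathway_ids"]).to_csv(
        edges_path, sep="\t", index=False
    )
    nrows = [
        (n, d["kind"], d["differential"], d["weight"])
        for n, d in sorted(net.graph.nodes(data=True))
    ]
    pd.DataFrame(nrows, columns=["id", "kind", "differential", "weight"]).to_csv(
        nodes_path, sep="\t", index=False
    )


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    """GraphML export (attributes flattened to strings where needed)."""
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(n, kind=d["kind"], differential=bool(d["differential"]), weight=int(d["weight"]))
    for a, b, d in net.graph.edges(data=True):
        g.add_edge(a, b, weight=int(d["weight"]), subpathways=";".join(sorted(d["subpathways"])))
    nx.write_graphml(g, path)
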