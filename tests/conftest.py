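from __future__ import annotations

import networkx as nx
import pytest

from mirsubpath.pathway_io import DifferentialSet, PathwayGraph
from mirsubpath.rmpg import GENE, MIRNA, MIRNA_TARGET, RMPG


def make_pathway(pathway_id: str, edges, nodes=(), species: str = "hsa", name: str | None = None) -> PathwayGraph:
    """Small pathway graph from an edge list; edges may carry compound labels."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for edge in edges:
        if len(edge) == 3:
            a, b, compounds = edge
        else:
            a, b = edge
            compounds = set()
        g.add_edge(a, b, compounds=set(compounds))
    return PathwayGraph(pathway_id=pathway_id, name=name or pathway_id, species=species, graph=g)


def make_rmpg(pathway_id: str, gene_edges, mirna_edges=(), isolated_genes=(), species: str = "hsa") -> RMPG:
    """RMPG from explicit gene-gene and (miRNA, target) edge lists."""
    g = nx.Graph()
    g.add_nodes_from(isolated_genes, kind=GENE)
    for a, b in gene_edges:
        g.add_node(a, kind=GENE)
        g.add_node(b, kind=GENE)
        g.add_edge(a, b, compounds=set())
    for m, t in mirna_edges:
        g.add_node(m, kind=MIRNA)
        if t not in g:
            g.add_node(t, kind=GENE)
        g.add_edge(m, t, kind=MIRNA_TARGET)
    return RMPG(pathway_id=pathway_id, name=pathway_id, species=species, graph=g)


def random_rmpg(rng, n_nodes: int, p_edge: float = 0.3, mirna_fraction: float = 0.25,
                pathway_id: str = "path:r") -> RMPG:
    """Random connected-ish mixed-kind graph for oracle comparisons.

    MiRNA nodes only ever connect to gene nodes (as in a real RMPG); gene
    nodes connect among themselves.
    """
    genes = [f"g{i}" for i in range(max(2, int(n_nodes * (1 - mirna_fraction))))]
    mirnas = [f"m{i}" for i in range(n_nodes - len(genes))]
    g = nx.Graph()
    g.add_nodes_from(genes, kind=GENE)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if rng.random() < p_edge:
                g.add_edge(a, b, compounds=set())
    for m in mirnas:
        k = 1 + int(rng.integers(0, 3))
        targets = rng.choice(genes, size=min(k, len(genes)), replace=False)
        g.add_node(m, kind=MIRNA)
        for t in targets:
            g.add_edge(m, str(t), kind=MIRNA_TARGET)
    return RMPG(pathway_id=pathway_id, name=pathway_id, species="hsa", graph=g)


@pytest.fixture
def diffset():
    def _make(genes=(), mirnas=(), bg_genes: int = 1000, bg_mirnas: int = 100) -> DifferentialSet:
        return DifferentialSet(
            genes=frozenset(genes), mirnas=frozenset(mirnas),
            background_gene_count=bg_genes, background_mirna_count=bg_mirnas,
        )

    return _make
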