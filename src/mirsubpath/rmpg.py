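"""Reconstructed metabolic pathway graphs (RMPGs).

An RMPG is a metabolic pathway graph augmented with the miRNAs that
regulate it: each miRNA with at least one experimentally verified target
among the pathway's genes is embedded as a node linked to those targets.
The resulting graph mixes gene and miRNA nodes, gene-gene edges (compound
labelled) and miRNA-target edges, and is the substrate on which subpathway
location operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .pathway_io import (
    InteractionRecord,
    PathwayGraph,
    read_exchange_tsv,
    write_exchange_tsv,
)

GENE = "gene"
MIRNA = "mirna"
MIRNA_TARGET = "mirna_target"


@dataclass
class RMPG:
    """A pathway graph with embedded miRNA regulators.

    Nodes carry a ``kind`` attribute (``gene`` or ``mirna``); miRNA-target
    edges carry ``kind="mirna_target"`` while gene-gene edges keep their
    compound labels. Edges are undirected throughout so that shortest-path
    distances treat the regulatory layer and the metabolic layer as one
    graph; the regulatory direction (miRNA represses target) is implicit in
    the node kinds.
    """

    pathway_id: str
    name: str
    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("kind") not in (GENE, MIRNA):
                raise ValueError(f"node {node!r} lacks a gene/mirna kind tag")
        for m in self.mirna_nodes:
            if self.graph.degree(m) == 0:
                raise ValueError(f"miRNA node {m!r} has no target edge")

    @property
    def gene_nodes(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d["kind"] == GENE)

    @property
    def mirna_nodes(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d["kind"] == MIRNA)

    @property
    def mirna_edges(self) -> frozenset[tuple[str, str]]:
        """miRNA-target edges as (miRNA id, gene id) pairs."""
        out = set()
        for a, b, d in self.graph.edges(data=True):
            if d.get("kind") == MIRNA_TARGET:
                if self.graph.nodes[a]["kind"] == MIRNA:
                    out.add((a, b))
                else:
                    out.add((b, a))
        return frozenset(out)

    @property
    def gene_gene_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            tuple(sorted((a, b)))
            for a, b, d in self.graph.edges(data=True)
            if d.get("kind") != MIRNA_TARGET
        )

    @property
    def target_genes(self) -> frozenset[str]:
        """Genes with at least one incident miRNA-target edge."""
        return frozenset(g for _, g in self.mirna_edges)

    def node_kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]


def embed_mirnas(pathway: PathwayGraph, interactions: Iterable[InteractionRecord]) -> RMPG:
    """Embed miRNA regulators into a pathway graph.

    For every miRNA with at least one verified target among the pathway's
    genes, a miRNA node is added with one undirected edge per in-pathway
    target. MiRNAs without in-pathway targets are omitted; the gene-gene
    structure is copied untouched. Interactions are expected to be
    deduplicated and already restricted to low-throughput evidence for the
    pathway's species.
    """
    graph = nx.Graph()
    graph.add_nodes_from(pathway.graph.nodes, kind=GENE)
    for a, b, d in pathway.graph.edges(data=True):
        graph.add_edge(a, b, compounds=set(d.get("compounds", ())))
    genes = set(pathway.graph.nodes)
    for rec in interactions:
        if rec.target_gene in genes:
            if rec.mirna_id not in graph:
                graph.add_node(rec.mirna_id, kind=MIRNA)
            graph.add_edge(rec.mirna_id, rec.target_gene, kind=MIRNA_TARGET)
    return RMPG(pathway_id=pathway.pathway_id, name=pathway.name, species=pathway.species, graph=graph)


@dataclass
class RMPGSummary:
    """Composition counts per RMPG and their collection-level means."""

    per_graph: pd.DataFrame
    means: pd.Series
    n_distinct_mirnas_global: int

    _COUNT_COLUMNS = [
        "n_nodes",
        "n_genes",
        "n_mirnas",
        "n_targets",
        "n_gene_gene_edges",
        "n_mirna_target_edges",
    ]


def summarize(rmpgs: Sequence[RMPG]) -> RMPGSummary:
    """Per-RMPG node/edge composition counts plus collection means.

    A miRNA embedded in several pathways is counted once per pathway in the
    per-graph table and once globally in ``n_distinct_mirnas_global``.
    """
    if not rmpgs:
        raise ValueError("summarize requires a non-empty RMPG collection")
    rows = {}
    all_mirnas: set[str] = set()
    for r in rmpgs:
        mirnas = r.mirna_nodes
        all_mirnas |= mirnas
        rows[r.pathway_id] = {
            "n_nodes": r.graph.number_of_nodes(),
            "n_genes": len(r.gene_nodes),
            "n_mirnas": len(mirnas),
            "n_targets": len(r.target_genes),
            "n_gene_gene_edges": len(r.gene_gene_edges),
            "n_mirna_target_edges": len(r.mirna_edges),
        }
    per_graph = pd.DataFrame.from_dict(rows, orient="index")[RMPGSummary._COUNT_COLUMNS]
    per_graph.index.name = "pathway_id"
    return RMPGSummary(
        per_graph=per_graph,
        means=per_graph.mean(),
        n_distinct_mirnas_global=len(all_mirnas),
    )


def write_rmpgs(rmpgs: Sequence[RMPG], path: str | Path) -> None:
    """Serialize RMPGs to the exchange TSV (node kinds in the labels column)."""
    write_exchange_tsv(rmpgs, path)


def read_rmpgs(path: str | Path) -> list[RMPG]:
    """Read RMPGs back from the exchange TSV; round-trips losslessly."""
    out = []
    for pg in read_exchange_tsv(path):
        graph = pg.graph
        for a, b in graph.edges:
            kinds = {graph.nodes[a]["kind"], graph.nodes[b]["kind"]}
            if MIRNA in kinds:
                graph.edges[a, b]["kind"] = MIRNA_TARGET
                graph.edges[a, b].pop("compounds", None)
        out.append(RMPG(pathway_id=pg.pathway_id, name=pg.name, species=pg.species, graph=graph))
    return out
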