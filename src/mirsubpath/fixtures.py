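"""Seeded synthetic pathway/interaction/signature generator.

Emulates the shape of a metabolic pathway collection with an embedded
regulatory layer: connected random gene graphs at realistic density
(roughly 2.5 gene-gene edges per gene, matching the observed ~138 edges on
~50-gene metabolic pathway graphs), a pool of miRNAs targeting pathway
genes through low-throughput-style interaction records, and differential
gene/miRNA lists at genome scale. One pathway carries a *planted* enriched
subregion — a connected set of nodes with high signature density, targeted
by several differential miRNAs — whose identity is returned as ground
truth, so recovery can be measured end to end with no external downloads.

The generator is fully deterministic for a fixed spec and seed: all
sampling is driven by one numpy generator over sorted id lists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .pathway_io import (
    LOW_THROUGHPUT,
    HIGH_THROUGHPUT,
    DifferentialSet,
    InteractionRecord,
    PathwayGraph,
    write_exchange_tsv,
)

import pandas as pd


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults describe the standard test condition: 12 pathways of 30-60
    genes at density 2.5 edges per gene, 40 candidate miRNAs with 2-6
    targets each, genome-scale universes (20000 genes, 1000 miRNAs) and
    genome-scale differential lists (~3000 genes, ~350 miRNAs including
    off-pathway identifiers), with a 12-node planted region at signature
    density 0.9 against a 0.05 background.
    """

    n_pathways: int = 12
    genes_per_pathway: tuple[int, int] = (30, 60)
    edge_density: float = 2.5
    n_mirnas: int = 40
    targets_per_mirna: tuple[int, int] = (2, 6)
    planted_pathway_index: int = 0
    planted_region_size: int = 12
    planted_mirna_count: int = 3
    planted_signature_fraction: float = 0.9
    background_signature_fraction: float = 0.05
    background_gene_count: int = 20000
    background_mirna_count: int = 1000
    offpathway_diff_genes: int = 3000
    offpathway_diff_mirnas: int = 350
    species: str = "hsa"
    high_throughput_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_pathway_index < self.n_pathways:
            raise ValueError("planted_pathway_index out of range")
        if self.planted_region_size > self.genes_per_pathway[0]:
            raise ValueError("planted region larger than the smallest possible pathway")
        for frac in (self.planted_signature_fraction, self.background_signature_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("signature fractions must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery scoring."""

    pathway_id: str
    planted_genes: frozenset[str]
    planted_mirnas: frozenset[str]

    @property
    def planted_nodes(self) -> frozenset[str]:
        return self.planted_genes | self.planted_mirnas


@dataclass
class FixtureData:
    pathways: list[PathwayGraph]
    interactions: list[InteractionRecord]
    diff: DifferentialSet
    truth: GroundTruth


def _connected_random_graph(nodes: Sequence[str], n_edges: int, rng: np.random.Generator) -> nx.Graph:
    """Random connected graph: a random spanning tree plus uniform extra edges."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = list(rng.permutation(list(nodes)))
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        g.add_edge(order[i], order[j])
    max_edges = len(nodes) * (len(nodes) - 1) // 2
    target = min(max(n_edges, len(nodes) - 1), max_edges)
    node_list = sorted(nodes)
    while g.number_of_edges() < target:
        a, b = rng.choice(node_list, size=2, replace=False)
        if not g.has_edge(a, b):
            g.add_edge(a, b)
    return g


def _bfs_region(g: nx.Graph, start: str, size: int, rng: np.random.Generator) -> frozenset[str]:
    """A connected region grown breadth-first with randomised frontier order."""
    region = [start]
    seen = {start}
    frontier = [start]
    while len(region) < size and frontier:
        node = frontier.pop(0)
        nbrs = sorted(set(g.neighbors(node)) - seen)
        nbrs = list(rng.permutation(nbrs)) if nbrs else []
        for nb in nbrs:
            if len(region) >= size:
                break
            region.append(nb)
            seen.add(nb)
            frontier.append(nb)
    return frozenset(region[:size])


def _floor_sample(items: Sequence[str], fraction: float, rng: np.random.Generator) -> set[str]:
    items = sorted(items)
    k = math.floor(fraction * len(items))
    if k == 0:
        return set()
    return {str(x) for x in rng.choice(items, size=k, replace=False)}


def generate(spec: FixtureSpec) -> FixtureData:
    """Generate one synthetic study (pathways, interactions, signatures, truth)."""
    rng = np.random.default_rng(spec.seed)

    # Pathway graphs with compound-labelled edges.
    pathways: list[PathwayGraph] = []
    compound_counter = 0
    for i in range(spec.n_pathways):
        n_genes = int(rng.integers(spec.genes_per_pathway[0], spec.genes_per_pathway[1] + 1))
        nodes = [f"G{i:03d}.{j:03d}" for j in range(n_genes)]
        g = _connected_random_graph(nodes, round(spec.edge_density * n_genes), rng)
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            compound_counter += 1
            g.edges[a, b]["compounds"] = {f"cpd:C{compound_counter:05d}"}
        pathways.append(
            PathwayGraph(
                pathway_id=f"path:{i:05d}", name=f"synthetic pathway {i}",
                species=spec.species, graph=g,
            )
        )

    planted_pg = pathways[spec.planted_pathway_index]
    all_genes = sorted(set().union(*(p.graph.nodes for p in pathways)))

    # Planted connected region and its signatures.
    start = str(rng.choice(sorted(planted_pg.graph.nodes)))
    planted_genes = _bfs_region(planted_pg.graph, start, spec.planted_region_size, rng)
    if len(planted_genes) < spec.planted_region_size:
        raise ValueError("could not grow a connected planted region of the requested size")
    n_planted_sig = math.floor(spec.planted_signature_fraction * len(planted_genes))
    planted_sig_genes = {
        str(x) for x in rng.choice(sorted(planted_genes), size=n_planted_sig, replace=False)
    }

    # Background gene signatures everywhere else.
    other_genes = sorted(set(all_genes) - planted_genes)
    background_sig_genes = _floor_sample(other_genes, spec.background_signature_fraction, rng)

    # MiRNA pool: planted miRNAs target the planted region; the rest target
    # genes anywhere.  A slice of records is duplicated with high-throughput
    # evidence to exercise the filtering path.
    interactions: list[InteractionRecord] = []
    mirna_ids = [f"{spec.species}-miR-S{j:03d}" for j in range(spec.n_mirnas)]
    planted_mirnas = set(mirna_ids[: spec.planted_mirna_count])
    for j, mid in enumerate(mirna_ids):
        n_targets = int(rng.integers(spec.targets_per_mirna[0], spec.targets_per_mirna[1] + 1))
        if mid in planted_mirnas:
            pool = sorted(planted_genes)
            n_targets = min(n_targets, len(pool))
        else:
            pool = all_genes
        targets = rng.choice(pool, size=n_targets, replace=False)
        for t in targets:
            interactions.append(
                InteractionRecord(
                    mirna_id=mid, target_gene=str(t), species=spec.species,
                    evidence=LOW_THROUGHPUT, source="synthdb",
                )
            )
    # High-throughput-only decoy records (dropped by the evidence filter).
    n_decoys = math.floor(spec.high_throughput_fraction * len(interactions))
    for _ in range(n_decoys):
        mid = str(rng.choice(mirna_ids))
        t = str(rng.choice(all_genes))
        interactions.append(
            InteractionRecord(
                mirna_id=mid, target_gene=t, species=spec.species,
                evidence=HIGH_THROUGHPUT, source="synthdb_ht",
            )
        )

    # Differential miRNAs: planted ones plus a background fraction of the rest.
    other_mirnas = sorted(set(mirna_ids) - planted_mirnas)
    background_sig_mirnas = _floor_sample(other_mirnas, spec.background_signature_fraction, rng)

    off_genes = {f"OFFG{j:05d}" for j in range(spec.offpathway_diff_genes)}
    off_mirnas = {f"{spec.species}-miR-OFF{j:04d}" for j in range(spec.offpathway_diff_mirnas)}
    diff = DifferentialSet(
        genes=frozenset(planted_sig_genes | background_sig_genes | off_genes),
        mirnas=frozenset(planted_mirnas | background_sig_mirnas | off_mirnas),
        background_gene_count=spec.background_gene_count,
        background_mirna_count=spec.background_mirna_count,
    )
    truth = GroundTruth(
        pathway_id=planted_pg.pathway_id,
        planted_genes=planted_genes,
        planted_mirnas=frozenset(planted_mirnas),
    )
    return FixtureData(pathways=pathways, interactions=interactions, diff=diff, truth=truth)


def write_fixture(data: FixtureData, directory: str | Path) -> dict[str, Path]:
    """Write a fixture to plain-text files re-readable by the IO module.

    Emits the pathway exchange TSV, the interaction TSV, one-id-per-line
    differential lists, and a ground-truth manifest (JSON) that also
    records the background universe sizes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pathways": directory / "pathways.tsv",
        "interactions": directory / "interactions.tsv",
        "diff_genes": directory / "diff_genes.txt",
        "diff_mirnas": directory / "diff_mirnas.txt",
        "manifest": directory / "manifest.json",
    }
    write_exchange_tsv(data.pathways, paths["pathways"])
    pd.DataFrame(
        [(r.mirna_id, r.target_gene, r.species, r.evidence, r.source) for r in data.interactions],
        columns=["mirna", "target", "species", "evidence", "source"],
    ).to_csv(paths["interactions"], sep="\t", index=False)
    paths["diff_genes"].write_text("".join(f"{g}\n" for g in sorted(data.diff.genes)))
    paths["diff_mirnas"].write_text("".join(f"{m}\n" for m in sorted(data.diff.mirnas)))
    manifest = {
        "planted_pathway_id": data.truth.pathway_id,
        "planted_genes": sorted(data.truth.planted_genes),
        "planted_mirnas": sorted(data.truth.planted_mirnas),
        "background_gene_count": data.diff.background_gene_count,
        "background_mirna_count": data.diff.background_mirna_count,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
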