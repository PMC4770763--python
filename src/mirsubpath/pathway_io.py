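"""Readers and writers for pathway structures and miRNA-target interaction data.

Metabolic pathways arrive either as KGML (the KEGG pathway XML dialect) or as
a simplified tab-separated exchange format; both are normalised into
:class:`PathwayGraph` objects — undirected graphs whose nodes are gene
identifiers and whose edges carry the compound(s) mediating the connection.
MiRNA-target interaction tables, differential molecule lists, and
precursor-to-mature miRNA maps are read from plain tab-separated text.

Gene and miRNA identifiers are treated as opaque strings: no identifier
conversion is performed, so callers must supply pathway files, interaction
tables and differential lists in one consistent namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Organism codes with curated metabolic pathway collections.
SPECIES = frozenset({"cel", "dme", "dre", "hsa", "mmu", "rno"})

LOW_THROUGHPUT = "low_throughput"
HIGH_THROUGHPUT = "high_throughput"

_EXCHANGE_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "species",
    "record",
    "a",
    "b",
    "labels",
]


class PathwayParseError(ValueError):
    """Raised when a pathway document cannot be interpreted."""


@dataclass
class PathwayGraph:
    """An undirected metabolic pathway graph with genes as nodes.

    Edges join genes that are adjacent in the pathway — either directly
    related or catalysing consecutive reactions — and carry the set of
    compound identifiers mediating the link as the ``compounds`` edge
    attribute (possibly empty).
    """

    pathway_id: str
    name: str
    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species code {self.species!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop edges not allowed: {loops[:3]}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_compounds(self, a: str, b: str) -> frozenset[str]:
        return frozenset(self.graph.edges[a, b].get("compounds", ()))


@dataclass(frozen=True)
class InteractionRecord:
    """One experimentally supported miRNA-target pair."""

    mirna_id: str
    target_gene: str
    species: str
    evidence: str
    source: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.target_gene:
            raise ValueError("mirna_id and target_gene must be non-empty")
        if self.evidence not in (LOW_THROUGHPUT, HIGH_THROUGHPUT):
            raise ValueError(f"evidence must be low_throughput or high_throughput, got {self.evidence!r}")


@dataclass(frozen=True)
class DifferentialSet:
    """Differential genes and mature miRNAs with their background universes.

    ``background_gene_count`` / ``background_mirna_count`` are the sizes of
    the genome and miRNAome the differential lists were drawn from; they are
    the defaults for the enrichment universes m_g and m_mir.
    """

    genes: frozenset[str]
    mirnas: frozenset[str]
    background_gene_count: int
    background_mirna_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "mirnas", frozenset(self.mirnas))
        if self.background_gene_count <= 0 or self.background_mirna_count <= 0:
            raise ValueError("background universe sizes must be positive")
        if len(self.genes) > self.background_gene_count:
            raise ValueError("more differential genes than the background gene universe")
        if len(self.mirnas) > self.background_mirna_count:
            raise ValueError("more differential miRNAs than the background miRNAome")

    @property
    def molecules(self) -> frozenset[str]:
        return self.genes | self.mirnas


def _entry_gene_ids(entry: ElementTree.Element) -> list[str]:
    # A KGML gene entry may carry several gene ids in one space-separated
    # name attribute; each becomes its own node.
    return entry.get("name", "").split()


def parse_kgml(document: str, species: str) -> PathwayGraph:
    """Convert a KGML pathway document into a :class:`PathwayGraph`.

    Gene entries become nodes (multi-gene entries are split, every id
    inheriting the entry's relations). An undirected edge joins two genes
    when an ECrel relation links their entries (the relation's compound
    subtype supplies the edge label) or when they catalyse consecutive
    reactions, i.e. a product of one reaction is a substrate of the other;
    reversible reactions are considered in both orientations. Compound
    entries never become nodes.
    """
    try:
        root = ElementTree.fromstring(document)
    except ElementTree.ParseError as exc:
        raise PathwayParseError(f"malformed KGML document: {exc}") from exc
    if root.tag != "pathway":
        raise PathwayParseError(f"expected <pathway> root element, found <{root.tag}>")

    pathway_id = root.get("name", root.get("number", "path:unknown"))
    name = root.get("title", pathway_id)

    gene_entries: dict[str, list[str]] = {}  # entry id -> gene ids
    compound_names: dict[str, str] = {}  # entry id -> compound id
    for entry in root.iter("entry"):
        etype = entry.get("type")
        eid = entry.get("id", "")
        if etype == "gene":
            gene_entries[eid] = _entry_gene_ids(entry)
        elif etype == "compound":
            compound_names[eid] = entry.get("name", eid)

    graph = nx.Graph()
    for ids in gene_entries.values():
        graph.add_nodes_from(ids)

    def _add_edge(a: str, b: str, compounds: Iterable[str]) -> None:
        if a == b:
            return
        if graph.has_edge(a, b):
            graph.edges[a, b]["compounds"] |= set(compounds)
        else:
            graph.add_edge(a, b, compounds=set(compounds))

    # ECrel relations: enzyme-enzyme links mediated by a compound.
    for relation in root.iter("relation"):
        if relation.get("type") != "ECrel":
            continue
        e1, e2 = relation.get("entry1", ""), relation.get("entry2", "")
        if e1 not in gene_entries or e2 not in gene_entries:
            continue
        compounds = [
            compound_names.get(st.get("value", ""), st.get("value", ""))
            for st in relation.iter("subtype")
            if st.get("name") == "compound"
        ]
        for a in gene_entries[e1]:
            for b in gene_entries[e2]:
                _add_edge(a, b, compounds)

    # Consecutive reactions: product of one is a substrate of the next.
    reactions: list[tuple[set[str], set[str], bool, str]] = []
    for reaction in root.iter("reaction"):
        subs = {s.get("name", "") for s in reaction.iter("substrate")}
        prods = {p.get("name", "") for p in reaction.iter("product")}
        reversible = reaction.get("type") == "reversible"
        reactions.append((subs, prods, reversible, reaction.get("name", "")))

    def _reaction_genes(rname: str) -> list[str]:
        hits: list[str] = []
        for entry in root.iter("entry"):
            if entry.get("type") != "gene":
                continue
            if rname and rname in entry.get("reaction", "").split():
                hits.extend(_entry_gene_ids(entry))
        return hits

    rgenes = {rname: _reaction_genes(rname) for *_, rname in reactions}
    for i, (subs1, prods1, rev1, n1) in enumerate(reactions):
        out1 = prods1 | (subs1 if rev1 else set())
        for subs2, prods2, rev2, n2 in reactions[i + 1 :]:
            in2 = subs2 | (prods2 if rev2 else set())
            in1 = subs1 | (prods1 if rev1 else set())
            out2 = prods2 | (subs2 if rev2 else set())
            shared = (out1 & in2) | (out2 & in1)
            if not shared:
                continue
            for a in rgenes[n1]:
                for b in rgenes[n2]:
                    _add_edge(a, b, shared)

    if not graph.nodes:
        logger.warning("pathway %s contains no gene entries; returning an empty graph", pathway_id)
    return PathwayGraph(pathway_id=pathway_id, name=name, species=species, graph=graph)


# ---------------------------------------------------------------------------
# Simplified pathway exchange format (TSV)
# ---------------------------------------------------------------------------

def write_exchange_tsv(
    graphs: Sequence, path: str | Path, node_kinds: Mapping[str, Mapping[str, str]] | None = None
) -> None:
    """Write pathway graphs to the simplified exchange TSV.

    One row per node (``record=node``, kind in the ``labels`` column) and one
    per edge (``record=edge``, semicolon-joined compound labels). Accepts
    :class:`PathwayGraph` objects or anything exposing ``pathway_id``,
    ``name``, ``species`` and ``graph``; node kinds default to ``gene`` and
    may be overridden per pathway via *node_kinds*.
    """
    rows = []
    for pg in graphs:
        kinds = (node_kinds or {}).get(pg.pathway_id, {})
        for node in sorted(pg.graph.nodes):
            kind = kinds.get(node, pg.graph.nodes[node].get("kind", "gene"))
            rows.append((pg.pathway_id, pg.name, pg.species, "node", node, "", kind))
        for a, b in sorted(tuple(sorted(e)) for e in pg.graph.edges):
            labels = ";".join(sorted(pg.graph.edges[a, b].get("compounds", ())))
            rows.append((pg.pathway_id, pg.name, pg.species, "edge", a, b, labels))
    frame = pd.DataFrame(rows, columns=_EXCHANGE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_exchange_tsv(path: str | Path) -> list[PathwayGraph]:
    """Read the simplified exchange TSV back into :class:`PathwayGraph` objects.

    Node kind tags are preserved as the ``kind`` node attribute, so the same
    reader round-trips both plain pathway graphs and miRNA-augmented ones.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EXCHANGE_COLUMNS if c not in frame.columns]
    if missing:
        raise PathwayParseError(f"exchange TSV missing columns: {missing}")
    graphs: list[PathwayGraph] = []
    for pid, block in frame.groupby("pathway_id", sort=True):
        graph = nx.Graph()
        for row in block.itertuples(index=False):
            if row.record == "node":
                graph.add_node(row.a, kind=row.labels or "gene")
            elif row.record == "edge":
                compounds = set(filter(None, row.labels.split(";")))
                graph.add_edge(row.a, row.b, compounds=compounds)
            else:
                raise PathwayParseError(f"unknown record type {row.record!r} in {path}")
        first = block.iloc[0]
        graphs.append(
            PathwayGraph(pathway_id=pid, name=first["pathway_name"], species=first["species"], graph=graph)
        )
    return graphs


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "mirna": "mirna",
    "target": "target",
    "species": "species",
    "evidence": "evidence",
    "source": "source",
}


def read_interactions(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[InteractionRecord]:
    """Read a tab-separated miRNA-target interaction table.

    *columns* maps the logical names (mirna, target, species, evidence,
    source) to the table's actual header names. Rows with an empty miRNA or
    target id are dropped and counted in a log summary; nothing aborts on
    dirty rows.
    """
    colmap = {**_DEFAULT_COLUMNS, **(columns or {})}
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in frame.columns]
    if missing:
        raise KeyError(f"interaction table missing required columns: {missing}")
    records: list[InteractionRecord] = []
    dropped = 0
    cols = {k: frame[v].astype(str).str.strip() for k, v in colmap.items()}
    for mirna, target, sp, evidence, source in zip(
        cols["mirna"], cols["target"], cols["species"], cols["evidence"], cols["source"]
    ):
        if not mirna or not target:
            dropped += 1
            continue
        records.append(
            InteractionRecord(
                mirna_id=mirna, target_gene=target, species=sp,
                evidence=evidence, source=source,
            )
        )
    if dropped:
        logger.info("read_interactions: dropped %d rows with missing mirna/target ids", dropped)
    return records


def deduplicate_interactions(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse duplicate (miRNA, target, species) records.

    Evidence resolves to low-throughput if any duplicate carried it — a pair
    confirmed once by a small-scale experiment stays confirmed — and the
    source database names are concatenated (sorted, semicolon-joined).
    """
    merged: dict[tuple[str, str, str], tuple[str, set[str]]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        key = (rec.mirna_id, rec.target_gene, rec.species)
        if key not in merged:
            merged[key] = (rec.evidence, set(s for s in rec.source.split(";") if s))
            order.append(key)
        else:
            evidence, sources = merged[key]
            if rec.evidence == LOW_THROUGHPUT:
                evidence = LOW_THROUGHPUT
            sources |= set(s for s in rec.source.split(";") if s)
            merged[key] = (evidence, sources)
    return [
        InteractionRecord(
            mirna_id=k[0], target_gene=k[1], species=k[2],
            evidence=merged[k][0], source=";".join(sorted(merged[k][1])),
        )
        for k in order
    ]


def filter_low_throughput(
    records: Iterable[InteractionRecord], species: str
) -> list[InteractionRecord]:
    """Keep only low-throughput-supported interactions of one species."""
    if species not in SPECIES:
        raise ValueError(f"unknown species code {species!r}")
    return [r for r in records if r.evidence == LOW_THROUGHPUT and r.species == species]


# ---------------------------------------------------------------------------
# Differential lists and precursor maps
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> frozenset[str]:
    """Read a one-identifier-per-line text file into a set."""
    with open(path) as handle:
        return frozenset(line.strip() for line in handle if line.strip())


def read_differential_set(
    genes_path: str | Path,
    mirnas_path: str | Path,
    background_gene_count: int,
    background_mirna_count: int,
) -> DifferentialSet:
    return DifferentialSet(
        genes=read_id_list(genes_path),
        mirnas=read_id_list(mirnas_path),
        background_gene_count=background_gene_count,
        background_mirna_count=background_mirna_count,
    )


def read_precursor_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (precursor, mature) TSV into a precursor map."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, header=None,
                        names=["precursor", "mature"], comment="#")
    out: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        if row.precursor and row.mature:
            out.setdefault(row.precursor, set()).add(row.mature)
    return {k: frozenset(v) for k, v in out.items()}


def map_precursors(
    mirna_ids: Iterable[str], pmap: Mapping[str, frozenset[str]]
) -> tuple[frozenset[str], frozenset[str]]:
    """Map precursor miRNA ids to the union of their mature forms.

    Returns ``(matures, unmapped)``: precursors absent from the map are
    reported in the second set rather than silently dropped.
    """
    matures: set[str] = set()
    unmapped: set[str] = set()
    for pre in mirna_ids:
        if pre in pmap:
            matures |= set(pmap[pre])
        else:
            unmapped.add(pre)
    return frozenset(matures), frozenset(unmapped)
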