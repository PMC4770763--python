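"""Locating miRNA-mediated subpathways with the lenient-distance rule.

Differential genes and miRNAs are mapped onto an RMPG as *signature nodes*.
Two signatures belong together when the shortest path between them crosses
at most ``n`` non-signature molecules; each qualifying pair contributes the
pair plus the interior nodes of every minimum-length path between them as a
candidate set. Overlapping candidate sets are merged transitively, the
merged sets are located back in the graph as induced subgraphs, and every
connected component with at least ``s`` nodes is reported as a subpathway.

With the defaults ``n=1, s=10`` this demands no more than one
non-differential molecule between any two differential molecules and keeps
only subregions large enough to plausibly dysregulate their parent pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .pathway_io import DifferentialSet
from .rmpg import RMPG


@dataclass(frozen=True)
class SubpathwayParams:
    """Lenient-distance parameters.

    n: maximum number of non-signature molecules tolerated strictly between
       two signatures on their shortest path (interior signature nodes are
       differential molecules and do not count against n).
    s: minimum node count for a reported subpathway.
    """

    n: int = 1
    s: int = 10

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.s < 1:
            raise ValueError("s must be at least 1")


@dataclass(frozen=True)
class SignatureSet:
    """Differential molecules present in one RMPG."""

    rmpg_id: str
    signature_nodes: frozenset[str]


@dataclass(frozen=True)
class Subpathway:
    """A connected induced subregion of an RMPG passing the size filter."""

    subpathway_id: str
    pathway_id: str
    member_nodes: frozenset[str]
    member_edges: frozenset[tuple[str, str]]
    signature_members: frozenset[str]


def map_signatures(rmpg: RMPG, diff: DifferentialSet) -> SignatureSet:
    """Intersect the differential gene/miRNA lists with the RMPG's nodes."""
    nodes = frozenset(rmpg.graph.nodes)
    return SignatureSet(rmpg_id=rmpg.pathway_id, signature_nodes=diff.molecules & nodes)


def candidate_sets(
    rmpg: RMPG, sig: SignatureSet, params: SubpathwayParams
) -> list[frozenset[str]]:
    """Candidate node sets from qualifying signature pairs.

    A pair qualifies when some minimum-length path between the two
    signatures carries at most ``params.n`` non-signature interior nodes;
    the emitted set is the pair plus the interior nodes of *all*
    minimum-length paths, so the result does not depend on traversal order.
    Each signature also contributes its singleton set, keeping isolated
    signatures available for merging.
    """
    graph = rmpg.graph
    signatures = sorted(sig.signature_nodes)
    missing = [s for s in signatures if s not in graph]
    if missing:
        raise ValueError(f"signature nodes absent from RMPG {rmpg.pathway_id}: {missing[:3]}")

    sets: list[frozenset[str]] = [frozenset({s}) for s in signatures]
    if len(signatures) < 2:
        return sets

    sigset = set(signatures)
    big = graph.number_of_nodes() + 1

    # Hop-count distances from every signature, for membership tests on
    # minimum-length paths (w lies on one iff d(u,w) + d(w,v) == d(u,v)).
    dist = {s: nx.single_source_shortest_path_length(graph, s) for s in signatures}

    # Composite-weight Dijkstra: cost big per hop plus 1 per non-signature
    # node entered.  Minimising it finds, among minimum-hop paths, the one
    # crossing the fewest non-signature interiors.
    def weight(u: str, v: str, d: dict) -> int:
        return big + (0 if v in sigset else 1)

    cost = {s: nx.single_source_dijkstra_path_length(graph, s, weight=weight) for s in signatures}

    for i, u in enumerate(signatures):
        du = dist[u]
        for v in signatures[i + 1 :]:
            if v not in du:
                continue  # different components
            hops = du[v]
            min_nonsig = cost[u][v] - big * hops
            if min_nonsig > params.n:
                continue
            dv = dist[v]
            members = {
                w for w, duw in du.items()
                if w != u and w != v and duw + dv.get(w, big * big) == hops
            }
            members |= {u, v}
            sets.append(frozenset(members))
    return sets


def merge_and_extract(
    rmpg: RMPG, candidates: Iterable[frozenset[str]], params: SubpathwayParams
) -> list[Subpathway]:
    """Merge overlapping candidate sets and extract qualifying subregions.

    Candidate sets sharing at least one node are merged transitively; each
    merged set is located in the RMPG as an induced subgraph, and every
    connected component with >= ``params.s`` nodes becomes one subpathway.
    Ordinal ids are assigned by descending component size, ties broken by
    the lexicographically smallest member id.
    """
    candidates = list(candidates)
    node_ids = set(rmpg.graph.nodes)
    for cand in candidates:
        stray = cand - node_ids
        if stray:
            raise ValueError(f"candidate nodes absent from RMPG {rmpg.pathway_id}: {sorted(stray)[:3]}")

    # Transitive merge via union-find keyed on nodes.
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cand in candidates:
        members = sorted(cand)
        for m in members:
            parent.setdefault(m, m)
        for m in members[1:]:
            ra, rb = find(members[0]), find(m)
            if ra != rb:
                parent[rb] = ra

    merged: dict[str, set[str]] = {}
    for node in parent:
        merged.setdefault(find(node), set()).add(node)

    components: list[frozenset[str]] = []
    for node_set in merged.values():
        sub = rmpg.graph.subgraph(node_set)
        for comp in nx.connected_components(sub):
            if len(comp) >= params.s:
                components.append(frozenset(comp))

    components.sort(key=lambda c: (-len(c), min(c)))
    out: list[Subpathway] = []
    for k, comp in enumerate(components, start=1):
        sub = rmpg.graph.subgraph(comp)
        edges = frozenset(tuple(sorted(e)) for e in sub.edges)
        out.append(
            Subpathway(
                subpathway_id=f"{rmpg.pathway_id}_{k}",
                pathway_id=rmpg.pathway_id,
                member_nodes=comp,
                member_edges=edges,
                signature_members=frozenset(),  # filled by locate()
            )
        )
    return out


def locate(rmpg: RMPG, diff: DifferentialSet, params: SubpathwayParams | None = None) -> list[Subpathway]:
    """Full lenient-distance subpathway location for one RMPG.

    Composes signature mapping, candidate-set construction and
    merge-and-extract; deterministic for fixed inputs.
    """
    params = params or SubpathwayParams()
    sig = map_signatures(rmpg, diff)
    cands = candidate_sets(rmpg, sig, params)
    located = merge_and_extract(rmpg, cands, params)
    return [
        Subpathway(
            subpathway_id=sp.subpathway_id,
            pathway_id=sp.pathway_id,
            member_nodes=sp.member_nodes,
            member_edges=sp.member_edges,
            signature_members=sp.member_nodes & sig.signature_nodes,
        )
        for sp in located
    ]
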