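"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: exact rational arithmetic for the
hypergeometric tail, and explicit path enumeration plus component merging
for subpathway location. They share no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx


def hypergeom_tail_enumeration(population: int, successes: int, draws: int, observed: int) -> float:
    """P(X >= observed) by direct summation in exact rational arithmetic."""
    if observed <= 0:
        return 1.0
    total = comb(population, draws)
    acc = Fraction(0)
    for k in range(observed, min(successes, draws) + 1):
        acc += Fraction(comb(successes, k) * comb(population - successes, draws - k), total)
    return float(acc)


def locate_bruteforce(graph: nx.Graph, signatures: set[str], n: int, s: int) -> list[frozenset[str]]:
    """Exhaustive lenient-distance subpathway location.

    Enumerates every minimum-length path between every signature pair, keeps
    pairs where some such path crosses at most *n* non-signature interior
    nodes, unions the interiors of all minimum-length paths with the
    endpoints, merges overlapping candidate sets transitively, extracts
    induced connected components and applies the size filter. Returns the
    member-node sets sorted by descending size then smallest member id.
    """
    sigs = sorted(sig for sig in signatures if sig in graph)
    candidates: list[frozenset[str]] = [frozenset({x}) for x in sigs]
    for i, u in enumerate(sigs):
        for v in sigs[i + 1 :]:
            if not nx.has_path(graph, u, v):
                continue
            paths = list(nx.all_shortest_paths(graph, u, v))
            qualifying = [
                p for p in paths
                if sum(1 for w in p[1:-1] if w not in signatures) <= n
            ]
            if not qualifying:
                continue
            members = {u, v}
            for p in paths:
                members.update(p[1:-1])
            candidates.append(frozenset(members))

    # Transitive merge via a meta-graph whose nodes are candidate indices.
    meta = nx.Graph()
    meta.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if candidates[i] & candidates[j]:
                meta.add_edge(i, j)
    components: list[frozenset[str]] = []
    for group in nx.connected_components(meta):
        merged = set()
        for idx in group:
            merged |= candidates[idx]
        for comp in nx.connected_components(graph.subgraph(merged)):
            if len(comp) >= s:
                components.append(frozenset(comp))
    components.sort(key=lambda c: (-len(c), min(c)))
    return components
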