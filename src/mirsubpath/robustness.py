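"""Perturbation protocols: how stable is the significant-pathway list?

Two stress tests are provided. Molecule deletion removes a fraction of the
differential genes and miRNAs (emulating signature loss between data sets
or platforms) and edge deletion removes a fraction of RMPG edges
(emulating pathway-annotation incompleteness). Each perturbed input is
re-analysed and the recalled fraction of a reference significant-pathway
list is summarised over replicates.

All randomness flows from a single master seed: per-replicate generators
are spawned deterministically, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pathway_io import DifferentialSet
from .rmpg import MIRNA, RMPG


@dataclass(frozen=True)
class PerturbationConfig:
    """Deletion protocol settings.

    deletion_fraction: fraction of molecules (or edges) removed, in [0, 1].
    replicates: number of independent perturbed copies (1000 reproduces the
        original protocol; scale down for quick checks).
    seed: master seed; replicate r uses the r-th spawned child generator.
    mode: ``molecules`` or ``edges``.
    edge_classes: ``pooled`` deletes from gene-gene and miRNA-target edges
        as one pool; ``separate`` removes the fraction within each class.
    """

    deletion_fraction: float
    replicates: int = 1000
    seed: int = 0
    mode: str = "molecules"
    edge_classes: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.deletion_fraction <= 1.0:
            raise ValueError("deletion_fraction must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in ("molecules", "edges"):
            raise ValueError("mode must be 'molecules' or 'edges'")
        if self.edge_classes not in ("pooled", "separate"):
            raise ValueError("edge_classes must be 'pooled' or 'separate'")


@dataclass(frozen=True)
class RecallSummary:
    """Per-replicate recalled fractions of a reference pathway list."""

    fractions: tuple[float, ...]
    mean: float
    reference_size: int


def _spawned_rngs(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def _sample_keep(items: Sequence[str], fraction: float, rng: np.random.Generator) -> frozenset[str]:
    items = sorted(items)
    k = math.floor(fraction * len(items))
    if k == 0:
        return frozenset(items)
    removed = set(rng.choice(items, size=k, replace=False))
    return frozenset(x for x in items if x not in removed)


def perturb_molecules(diff: DifferentialSet, cfg: PerturbationConfig) -> list[DifferentialSet]:
    """Randomly delete a fraction of the differential molecule lists.

    Per replicate, floor(fraction * |genes|) genes and
    floor(fraction * |mirnas|) miRNAs are removed uniformly without
    replacement; background universe sizes are unchanged.
    """
    if cfg.mode != "molecules":
        raise ValueError("perturb_molecules requires mode='molecules'")
    out = []
    for rng in _spawned_rngs(cfg.seed, cfg.replicates):
        out.append(
            DifferentialSet(
                genes=_sample_keep(sorted(diff.genes), cfg.deletion_fraction, rng),
                mirnas=_sample_keep(sorted(diff.mirnas), cfg.deletion_fraction, rng),
                background_gene_count=diff.background_gene_count,
                background_mirna_count=diff.background_mirna_count,
            )
        )
    return out


def _delete_edges(rmpg: RMPG, fraction: float, rng: np.random.Generator, edge_classes: str) -> RMPG:
    graph = rmpg.graph.copy()
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    if edge_classes == "pooled":
        pools = [edges]
    else:
        mirnas = rmpg.mirna_nodes
        pools = [
            [e for e in edges if not (set(e) & mirnas)],
            [e for e in edges if set(e) & mirnas],
        ]
    for pool in pools:
        k = math.floor(fraction * len(pool))
        if k:
            idx = rng.choice(len(pool), size=k, replace=False)
            graph.remove_edges_from(pool[i] for i in idx)
    # A miRNA exists in an RMPG only through its target edges; prune any
    # left isolated so the invariant holds on the perturbed graph.
    isolated = [n for n, d in graph.nodes(data=True) if d["kind"] == MIRNA and graph.degree(n) == 0]
    graph.remove_nodes_from(isolated)
    return RMPG(pathway_id=rmpg.pathway_id, name=rmpg.name, species=rmpg.species, graph=graph)


def perturb_edges(rmpgs: Sequence[RMPG], cfg: PerturbationConfig) -> list[list[RMPG]]:
    """Randomly delete a fraction of edges within each RMPG, per replicate."""
    if cfg.mode != "edges":
        raise ValueError("perturb_edges requires mode='edges'")
    out = []
    for rng in _spawned_rngs(cfg.seed, cfg.replicates):
        out.append([_delete_edges(r, cfg.deletion_fraction, rng, cfg.edge_classes) for r in rmpgs])
    return out


def recall_ratio(reference: Iterable[str], perturbed_runs: Sequence[Iterable[str]]) -> RecallSummary:
    """Fraction of the reference pathway list recovered per perturbed run."""
    ref = frozenset(reference)
    if not ref:
        raise ValueError("reference pathway list must be non-empty")
    fractions = tuple(len(frozenset(run) & ref) / len(ref) for run in perturbed_runs)
    mean = float(np.mean(fractions)) if fractions else 0.0
    return RecallSummary(fractions=fractions, mean=mean, reference_size=len(ref))


def molecule_robustness(
    rmpgs: Sequence[RMPG],
    diff: DifferentialSet,
    fractions: Sequence[float],
    replicates: int,
    seed: int,
    *,
    params=None,
    background_mode="genome",
    fdr_threshold: float = 0.01,
    method: str = "subpathway",
):
    """Full molecule-deletion protocol against a self-derived reference.

    For each deletion fraction, the differential lists are perturbed
    *replicates* times, the chosen method (``subpathway``, ``ora`` or
    ``mirna``) is re-run on each copy, and the recall of the unperturbed
    reference list (same method, same threshold) is summarised.  Returns a
    long-format DataFrame (fraction, replicate, recall) and a summary
    DataFrame (fraction, mean_recall).
    """
    import pandas as pd

    from . import pipeline

    rmpg_map = {r.pathway_id: r for r in rmpgs}

    def pathway_list(d: DifferentialSet) -> frozenset[str]:
        if method == "subpathway":
            return pipeline.identify(rmpg_map, d, params, background_mode).significant_pathways(fdr_threshold)
        ora_tab, mir_tab = pipeline.baselines(rmpg_map, d, background_mode)
        table = ora_tab if method == "ora" else mir_tab
        return pipeline.significant_pathways_baseline(table, fdr_threshold)

    reference = pathway_list(diff)
    if not reference:
        raise ValueError(f"reference list for method {method!r} is empty at FDR < {fdr_threshold}")

    long_rows = []
    summary_rows = []
    for frac in fractions:
        cfg = PerturbationConfig(deletion_fraction=frac, replicates=replicates, seed=seed, mode="molecules")
        runs = [pathway_list(d) for d in perturb_molecules(diff, cfg)]
        summary = recall_ratio(reference, runs)
        for rep, rec in enumerate(summary.fractions):
            long_rows.append({"fraction": frac, "replicate": rep, "recall": rec})
        summary_rows.append({"fraction": frac, "mean_recall": summary.mean})
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)


def edge_robustness(
    rmpgs: Sequence[RMPG],
    diff: DifferentialSet,
    fractions: Sequence[float],
    replicates: int,
    seed: int,
    *,
    params=None,
    background_mode="genome",
    fdr_threshold: float = 0.01,
    edge_classes: str = "pooled",
):
    """Full edge-deletion protocol (subpathway method only), same outputs as
    :func:`molecule_robustness`."""
    import pandas as pd

    from . import pipeline

    rmpg_map = {r.pathway_id: r for r in rmpgs}
    reference = pipeline.identify(rmpg_map, diff, params, background_mode).significant_pathways(fdr_threshold)
    if not reference:
        raise ValueError(f"reference list is empty at FDR < {fdr_threshold}")

    long_rows = []
    summary_rows = []
    for frac in fractions:
        cfg = PerturbationConfig(
            deletion_fraction=frac, replicates=replicates, seed=seed,
            mode="edges", edge_classes=edge_classes,
        )
        runs = []
        for collection in perturb_edges(list(rmpgs), cfg):
            cmap = {r.pathway_id: r for r in collection}
            runs.append(pipeline.identify(cmap, diff, params, background_mode).significant_pathways(fdr_threshold))
        summary = recall_ratio(reference, runs)
        for rep, rec in enumerate(summary.fractions):
            long_rows.append({"fraction": frac, "replicate": rep, "recall": rec})
        summary_rows.append({"fraction": frac, "mean_recall": summary.mean})
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)
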