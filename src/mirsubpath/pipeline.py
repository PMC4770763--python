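"""End-to-end orchestration: build RMPGs, identify subpathways, baselines.

Thin composition layer over the other modules; this is what the examples,
the command line and the robustness protocols call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import stats
from .pathway_io import (
    DifferentialSet,
    InteractionRecord,
    PathwayGraph,
    deduplicate_interactions,
    filter_low_throughput,
)
from .rmpg import RMPG, embed_mirnas
from .subpathway import Subpathway, SubpathwayParams, locate
from .stats import BackgroundMode, EnrichmentResult

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subpathway_id",
    "pathway_id",
    "pathway_name",
    "n_nodes",
    "n_genes",
    "n_mirnas",
    "n_signature_genes",
    "n_signature_mirnas",
    "m_g", "m_mir", "n_g", "n_mir", "t_g", "t_mir", "r_g", "r_mir",
    "p_value",
    "fdr",
    "members",
]


def build_rmpgs(
    pathways: Sequence[PathwayGraph],
    interactions: Iterable[InteractionRecord],
    species: str,
    *,
    prefiltered: bool = False,
) -> dict[str, RMPG]:
    """Deduplicate + evidence-filter interactions, then embed per pathway."""
    records = list(interactions)
    if not prefiltered:
        records = filter_low_throughput(deduplicate_interactions(records), species)
    if not records:
        logger.warning("no low-throughput interactions for species %s; RMPGs will carry no miRNAs", species)
    return {p.pathway_id: embed_mirnas(p, records) for p in pathways}


@dataclass
class IdentificationRun:
    """Everything one identification run produced."""

    subpathways: list[Subpathway]
    results: list[EnrichmentResult]
    table: pd.DataFrame

    def significant(self, fdr_threshold: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr_threshold]

    def significant_pathways(self, fdr_threshold: float = 0.01) -> frozenset[str]:
        """Pathways with at least one subpathway under the threshold."""
        return frozenset(self.significant(fdr_threshold)["pathway_id"])


def identify(
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
    params: SubpathwayParams | None = None,
    background_mode: BackgroundMode | str = BackgroundMode.GENOME,
) -> IdentificationRun:
    """Locate and score subpathways across an RMPG collection.

    Returns the located subpathways, their enrichment results (one joint
    BH family) and a ranked report table sorted by FDR then P.
    """
    params = params or SubpathwayParams()
    subpathways: list[Subpathway] = []
    for pid in sorted(rmpgs):
        subpathways.extend(locate(rmpgs[pid], diff, params))
    results = stats.score_subpathways(subpathways, rmpgs, diff, background_mode)
    rows = []
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    for res in results:
        sp = by_id[res.subpathway_id]
        rmpg = rmpgs[sp.pathway_id]
        c = res.counts
        rows.append(
            {
                "subpathway_id": sp.subpathway_id,
                "pathway_id": sp.pathway_id,
                "pathway_name": rmpg.name,
                "n_nodes": len(sp.member_nodes),
                "n_genes": c.t_g,
                "n_mirnas": c.t_mir,
                "n_signature_genes": c.r_g,
                "n_signature_mirnas": c.r_mir,
                "m_g": c.m_g, "m_mir": c.m_mir, "n_g": c.n_g, "n_mir": c.n_mir,
                "t_g": c.t_g, "t_mir": c.t_mir, "r_g": c.r_g, "r_mir": c.r_mir,
                "p_value": res.p_value,
                "fdr": res.fdr,
                "members": ";".join(sorted(sp.member_nodes)),
            }
        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not table.empty:
        table = table.sort_values(
            ["fdr", "p_value", "subpathway_id"], kind="mergesort"
        ).reset_index(drop=True)
    return IdentificationRun(subpathways=subpathways, results=results, table=table)


def _baseline_table(results: list[EnrichmentResult], rmpgs: Mapping[str, RMPG]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": r.subpathway_id,
            "pathway_name": rmpgs[r.subpathway_id].name,
            "m_g": r.counts.m_g, "m_mir": r.counts.m_mir,
            "n_g": r.counts.n_g, "n_mir": r.counts.n_mir,
            "t_g": r.counts.t_g, "t_mir": r.counts.t_mir,
            "r_g": r.counts.r_g, "r_mir": r.counts.r_mir,
            "p_value": r.p_value,
            "fdr": r.fdr,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["fdr", "p_value", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return table


def baselines(
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
    background_mode: BackgroundMode | str = BackgroundMode.GENOME,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-pathway baseline tables: (gene-only, miRNA-only)."""
    ora = stats.score_pathways_ora(rmpgs, diff, background_mode)
    mir = stats.score_pathways_mirna(rmpgs, diff, background_mode)
    return _baseline_table(ora, rmpgs), _baseline_table(mir, rmpgs)


def significant_pathways_baseline(table: pd.DataFrame, fdr_threshold: float = 0.01) -> frozenset[str]:
    if table.empty:
        return frozenset()
    return frozenset(table[table["fdr"] < fdr_threshold]["pathway_id"])


def compare_pathway_lists(
    list_a: Iterable[str], list_b: Iterable[str], universe: int
) -> tuple[frozenset[str], float]:
    """Shared pathways between two lists and the overlap significance."""
    a, b = frozenset(list_a), frozenset(list_b)
    if universe < max(len(a), len(b)):
        raise ValueError("universe smaller than one of the pathway lists")
    shared = a & b
    return shared, stats.overlap_pvalue(universe, len(a), len(b), len(shared))


def write_results(table: pd.DataFrame, path: str | Path, fdr_threshold: float | None = None) -> None:
    if fdr_threshold is not None and not table.empty:
        table = table[table["fdr"] < fdr_threshold]
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
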