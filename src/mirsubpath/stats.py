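"""Enrichment statistics for subpathways and complete pathways.

The central statistic pools genes and miRNAs into one hypergeometric urn:
a subpathway holding t_g genes and t_mir miRNAs, of which r_g + r_mir are
differential, is scored by the upper-tail probability of drawing at least
r_g + r_mir subpathway molecules when sampling n_g + n_mir differential
molecules from a universe of m_g genes plus m_mir miRNAs,

    P = 1 - sum_{k=0}^{r_g+r_mir-1}
            C(t_g+t_mir, k) C(m_g+m_mir-t_g-t_mir, n_g+n_mir-k)
            / C(m_g+m_mir, n_g+n_mir).

Gene-only and miRNA-only restrictions of the same tail give the two
complete-pathway baselines (classical over-representation analysis, and
the miRNA-centric variant that counts each pathway miRNA once regardless
of how many targets it has there). Benjamini-Hochberg adjustment and a
hypergeometric overlap test for comparing pathway lists round out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .pathway_io import DifferentialSet
from .rmpg import RMPG
from .subpathway import Subpathway


class BackgroundMode(str, Enum):
    """How the enrichment universes m_g / m_mir are chosen.

    ``genome``: caller-supplied whole-genome / whole-miRNAome sizes (taken
    from the DifferentialSet backgrounds). ``annotated``: the union of
    molecules across all RMPGs of the run, the common over-representation
    convention.
    """

    GENOME = "genome"
    ANNOTATED = "annotated"


@dataclass(frozen=True)
class EnrichmentCounts:
    """The eight integers feeding the pooled hypergeometric tail."""

    m_g: int
    m_mir: int
    n_g: int
    n_mir: int
    t_g: int
    t_mir: int
    r_g: int
    r_mir: int

    def validate(self) -> None:
        checks = [
            ("r_g <= min(n_g, t_g)", self.r_g <= min(self.n_g, self.t_g)),
            ("r_mir <= min(n_mir, t_mir)", self.r_mir <= min(self.n_mir, self.t_mir)),
            ("t_g <= m_g", self.t_g <= self.m_g),
            ("t_mir <= m_mir", self.t_mir <= self.m_mir),
            ("n_g <= m_g", self.n_g <= self.m_g),
            ("n_mir <= m_mir", self.n_mir <= self.m_mir),
            ("all counts >= 0", min(self.m_g, self.m_mir, self.n_g, self.n_mir,
                                    self.t_g, self.t_mir, self.r_g, self.r_mir) >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"enrichment count invariant violated: {name}")


@dataclass(frozen=True)
class EnrichmentResult:
    subpathway_id: str
    counts: EnrichmentCounts
    p_value: float
    fdr: float


def _tail(population: int, successes: int, draws: int, observed: int) -> float:
    """P(X >= observed), X ~ Hypergeometric(population, successes, draws)."""
    if observed <= 0:
        return 1.0
    p = float(hypergeom.sf(observed - 1, population, successes, draws))
    return min(1.0, max(0.0, p))


def subpathway_pvalue(counts: EnrichmentCounts) -> float:
    """Pooled gene+miRNA upper-tail hypergeometric probability.

    Computed via the survival function (stable for large tails) and
    clamped to [0, 1].
    """
    counts.validate()
    return _tail(
        population=counts.m_g + counts.m_mir,
        successes=counts.t_g + counts.t_mir,
        draws=counts.n_g + counts.n_mir,
        observed=counts.r_g + counts.r_mir,
    )


def ora_pvalue(m_g: int, n_g: int, t_g: int, r_g: int) -> float:
    """Gene-only over-representation tail at the complete-pathway level."""
    counts = EnrichmentCounts(m_g=m_g, m_mir=0, n_g=n_g, n_mir=0, t_g=t_g, t_mir=0, r_g=r_g, r_mir=0)
    counts.validate()
    return _tail(m_g, t_g, n_g, r_g)


def mirna_pvalue(m_mir: int, n_mir: int, t_mir: int, r_mir: int) -> float:
    """MiRNA-only tail: each pathway miRNA counts once, however many targets
    it has in the pathway."""
    counts = EnrichmentCounts(m_g=0, m_mir=m_mir, n_g=0, n_mir=n_mir, t_g=0, t_mir=t_mir, r_g=0, r_mir=r_mir)
    counts.validate()
    return _tail(m_mir, t_mir, n_mir, r_mir)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, order-preserving."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(ps, method="fdr_bh")
    return [float(x) for x in adjusted]


def overlap_pvalue(universe: int, size_a: int, size_b: int, shared: int) -> float:
    """Significance of the overlap between two pathway lists.

    Upper-tail P(X >= shared) for X ~ Hypergeometric(universe, size_a,
    size_b): the chance of sharing at least this many pathways if list B
    were drawn at random from the universe.
    """
    if shared < 0 or shared > min(size_a, size_b):
        raise ValueError("shared must satisfy 0 <= shared <= min(size_a, size_b)")
    if size_a > universe or size_b > universe:
        raise ValueError("list sizes cannot exceed the universe")
    if min(universe, size_a, size_b) < 0 or universe == 0:
        raise ValueError("universe must be positive and sizes non-negative")
    return _tail(universe, size_a, size_b, shared)


def _universes(
    rmpgs: Iterable[RMPG], diff: DifferentialSet, mode: BackgroundMode
) -> tuple[int, int, int, int]:
    """(m_g, m_mir, n_g, n_mir) under the chosen background mode."""
    if mode is BackgroundMode.GENOME:
        return (
            diff.background_gene_count,
            diff.background_mirna_count,
            len(diff.genes),
            len(diff.mirnas),
        )
    genes: set[str] = set()
    mirnas: set[str] = set()
    for r in rmpgs:
        genes |= r.gene_nodes
        mirnas |= r.mirna_nodes
    return len(genes), len(mirnas), len(diff.genes & genes), len(diff.mirnas & mirnas)


def score_subpathways(
    subpathways: Sequence[Subpathway],
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
    background_mode: BackgroundMode | str = BackgroundMode.GENOME,
) -> list[EnrichmentResult]:
    """Score each subpathway with the pooled tail; one joint BH family.

    FDR is adjusted over all subpathways of the run together, matching a
    single ranked result list per data set.
    """
    if not subpathways:
        return []
    mode = BackgroundMode(background_mode)
    m_g, m_mir, n_g, n_mir = _universes(rmpgs.values(), diff, mode)
    results: list[tuple[str, EnrichmentCounts, float]] = []
    for sp in subpathways:
        rmpg = rmpgs.get(sp.pathway_id)
        if rmpg is None:
            raise KeyError(f"subpathway {sp.subpathway_id} references unknown pathway {sp.pathway_id}")
        genes = {m for m in sp.member_nodes if rmpg.node_kind(m) == "gene"}
        mirnas = sp.member_nodes - genes
        counts = EnrichmentCounts(
            m_g=m_g, m_mir=m_mir, n_g=n_g, n_mir=n_mir,
            t_g=len(genes), t_mir=len(mirnas),
            r_g=len(genes & diff.genes), r_mir=len(mirnas & diff.mirnas),
        )
        results.append((sp.subpathway_id, counts, subpathway_pvalue(counts)))
    fdrs = bh_fdr([p for _, _, p in results])
    return [
        EnrichmentResult(subpathway_id=sid, counts=c, p_value=p, fdr=f)
        for (sid, c, p), f in zip(results, fdrs)
    ]


def score_pathways_ora(
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
    background_mode: BackgroundMode | str = BackgroundMode.GENOME,
) -> list[EnrichmentResult]:
    """Gene-only complete-pathway baseline: one test per RMPG."""
    mode = BackgroundMode(background_mode)
    m_g, _, n_g, _ = _universes(rmpgs.values(), diff, mode)
    rows = []
    for pid in sorted(rmpgs):
        genes = rmpgs[pid].gene_nodes
        counts = EnrichmentCounts(
            m_g=m_g, m_mir=0, n_g=n_g, n_mir=0,
            t_g=len(genes), t_mir=0, r_g=len(genes & diff.genes), r_mir=0,
        )
        rows.append((pid, counts, subpathway_pvalue(counts)))
    fdrs = bh_fdr([p for _, _, p in rows])
    return [
        EnrichmentResult(subpathway_id=pid, counts=c, p_value=p, fdr=f)
        for (pid, c, p), f in zip(rows, fdrs)
    ]


def score_pathways_mirna(
    rmpgs: Mapping[str, RMPG],
    diff: DifferentialSet,
    background_mode: BackgroundMode | str = BackgroundMode.GENOME,
) -> list[EnrichmentResult]:
    """MiRNA-only complete-pathway baseline: each pathway miRNA counts once."""
    mode = BackgroundMode(background_mode)
    _, m_mir, _, n_mir = _universes(rmpgs.values(), diff, mode)
    rows = []
    for pid in sorted(rmpgs):
        mirnas = rmpgs[pid].mirna_nodes
        counts = EnrichmentCounts(
            m_g=0, m_mir=m_mir, n_g=0, n_mir=n_mir,
            t_g=0, t_mir=len(mirnas), r_g=0, r_mir=len(mirnas & diff.mirnas),
        )
        rows.append((pid, counts, subpathway_pvalue(counts)))
    fdrs = bh_fdr([p for _, _, p in rows])
    return [
        EnrichmentResult(subpathway_id=pid, counts=c, p_value=p, fdr=f)
        for (pid, c, p), f in zip(rows, fdrs)
    ]
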