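# Methods

## Pathway graph reconstruction

Metabolic pathway structures are converted to undirected graphs with
genes as nodes. Two genes are joined when (a) an enzyme-enzyme (ECrel)
relation links their entries, with the mediating compound becoming the
edge label, or (b) they catalyse *consecutive* reactions — a product of
one reaction is a substrate of the other, with reversible reactions
considered in both orientations. The two sources are unioned because
metabolic pathway XML encodes adjacency in both places; compound entries
never become nodes. Pathway entries listing several gene identifiers are
split into one node per identifier, each inheriting the entry's
relations, so that the node namespace equals the gene-id namespace used
by interaction tables. This expansion is a convention of this package:
pathway formats do not prescribe one.

MiRNA-target interaction tables are deduplicated on (miRNA, target,
species); a merged record is low-throughput if *any* duplicate carried
low-throughput evidence, because a single small-scale validation
(reporter assay, qPCR) is not invalidated by additional high-throughput
observations. Only low-throughput-supported interactions of the run's
species are embedded. Embedding adds one miRNA node per miRNA with at
least one in-pathway target and one undirected edge per (miRNA,
in-pathway target) pair; miRNAs without in-pathway targets are omitted
from the graph but remain part of the background miRNAome universe,
which describes the measured miRNAome, not the embedded subset.

MiRNA-target edges are stored undirected and participate in shortest
paths identically to gene-gene edges: the located subregion is one mixed
graph, and regulatory direction (miRNA represses target) is recoverable
from node kinds for display.

## Lenient-distance subpathway location

Parameters: `n ≥ 0`, the maximum number of *non-signature* molecules
tolerated strictly between two signature nodes on their shortest path
(default 1); `s ≥ 1`, the minimum node count of a reported subpathway
(default 10). The defaults demand at most one non-differential molecule
between any two differential molecules and a subregion large enough to
plausibly dysregulate its parent pathway.

Decisions where the rule leaves room, all fixed here for determinism:

- *Signature interiors are free.* Interior nodes that are themselves
  signatures do not count against `n`; the rule constrains
  non-differential gaps only. Consequently, a pair qualifies when the
  minimum over all minimum-hop paths of the non-signature interior count
  is ≤ `n` (computed with a composite-weight Dijkstra: hop count first,
  non-signature interiors second).
- *All shortest paths contribute.* The candidate set of a qualifying
  pair is the two endpoints plus the interior nodes of **all**
  minimum-length paths between them (membership test:
  `d(u,w) + d(w,v) = d(u,v)`). Taking one arbitrary path would make the
  output depend on traversal order.
- *Singletons are seeded.* Every signature contributes its singleton
  candidate set before merging, so signatures in dense merged regions are
  not lost when no pair of theirs qualifies on its own.
- *Components are split.* Candidate sets sharing a node are merged
  transitively (union-find); each merged set is located in the graph as
  an induced subgraph, and each connected component of at least `s`
  nodes becomes one subpathway — a subpathway must be a connected piece
  of pathway, and merged sets can induce disconnected subgraphs.
- *Ordinal ids* (`<pathway>_1`, `_2`, …) are assigned by descending
  component size, ties broken by the lexicographically smallest member
  id. The suffix convention is standard; the ordering rule is this
  package's.

Monotonicity follows from the construction and is enforced by tests:
node coverage grows with `n`, and raising `s` only removes subpathways.

## Enrichment statistics

The pooled test treats genes and miRNAs as exchangeable draws from one
urn of size `m_g + m_mir`, with `t_g + t_mir` marked molecules and
`n_g + n_mir` draws, and reports the upper tail at `r_g + r_mir` — the
formula is implemented exactly in this pooled form (a two-urn product
would also be defensible but is not what the statistic specifies). Tails
are computed with the hypergeometric survival function (no `1 − CDF`
subtraction) and clamped to [0, 1]; count invariants are validated and
violations reported by name. Gene-only and miRNA-only restrictions give
the two complete-pathway baselines; the miRNA-only test takes `t_mir`
from the RMPG's distinct embedded miRNAs, counting each once regardless
of its number of in-pathway targets.

Two background modes set the universes: `genome` (caller-supplied
whole-genome and whole-miRNAome sizes; the default, matching the "entire
genome/miRNAome" reading of the statistic) and `annotated` (union of
molecules across the run's RMPGs, the common over-representation
convention, with differential lists intersected accordingly). Every
report records the mode and universe sizes.

FDR is Benjamini–Hochberg (the conventional choice for one ranked list
per data set), adjusted jointly over **all** subpathways of a run, not
per pathway. Pathway-list overlaps (reproducibility analysis) use the
same upper-tail hypergeometric on (universe, |A|, |B|, |A∩B|).

## Regulatory network merge

Significant subpathways are merged by unioning their member edges;
nothing new is inferred and compound labels are dropped in this view.
Edge weight = number of distinct contributing subpathways (provenance
ids retained); node weight = distinct cross-kind neighbours (targets of
a miRNA, regulators of a gene). Hub miRNAs are ranked by distinct-target
count, ties by subpathway count then id. The merge is strictly over
significant subpathway members; no surrounding pathway context is added.

## Robustness protocols

Molecule deletion removes `floor(f·|genes|)` genes and
`floor(f·|mirnas|)` miRNAs per replicate, uniformly without replacement;
the full analysis is re-run on each copy and recall of the unperturbed
reference list is averaged. The original protocol perturbs expression
profiles and re-derives differential lists; since differential calling
is out of scope here, the lists are perturbed directly — a documented
simplification that preserves the stress being tested (signature loss).
Edge deletion removes `floor(f·E)` edges per RMPG, pooled across
gene-gene and miRNA-target classes by default (`edge_classes="separate"`
deletes per class); miRNAs left without any target edge are pruned to
preserve the RMPG invariant. Recall is counted at the complete-pathway
level: a pathway is recalled if any of its subpathways passes the FDR
threshold. A master seed spawns per-replicate generators, so replicate
*r* is reproducible in isolation; at deletion fraction 0 recall is
exactly 1 by determinism.

The protocol's reference setting is 1000 replicates per deletion
fraction; the examples, tests and the acceptance script run 3–25
replicates on the 12-pathway synthetic study, which is enough to
estimate mean recall on a fixture this size.

## Synthetic studies

The generator emulates the *shape* of a metabolic pathway collection
with a regulatory layer: connected random graphs (random spanning tree
plus uniform extra edges — the simplest model guaranteeing the
connectivity the distance rule needs) of 30–60 genes at 2.5 gene-gene
edges per gene, matching the observed scale of real reconstructed
metabolic pathway graphs (~138 gene-gene edges, ~5–6 miRNAs each); 40
miRNAs with 2–6 low-throughput targets apiece plus ~15% high-throughput
decoy records to exercise evidence filtering; genome-scale universes
(20 000 genes, 1 000 miRNAs) and differential lists of ~3 000 genes and
~350 miRNAs, the magnitude typical of tumour-vs-normal comparisons. One
pathway carries a planted connected 12-node region at signature density
0.9 (background 0.05) targeted by 3 differential miRNAs; signature
counts follow a floor rule, so realized fractions are within one
molecule of the request.

What the fixtures do **not** emulate: real pathway topology (hub
enzymes, linear chains, pathway crosstalk through shared genes),
correlated differential expression, miRNA family structure, or
identifier noise. Passing tests therefore demonstrate correctness of the
algorithms and statistics under controlled conditions, not performance
on any particular real data set.

## Numerical and degenerate-input choices

- P-values clamped to [0, 1]; `r = 0` returns exactly 1.
- Empty signature sets, empty interaction tables and empty result lists
  are valid inputs/outputs everywhere (empty result is a result);
  readers log and skip dirty rows rather than aborting.
- All set-to-sequence conversions are sorted before any random sampling
  or output, making every pipeline stage byte-deterministic for a fixed
  seed.
- Result tables sort by FDR, then P, then id (stable mergesort).

## Known limitations

- No identifier conversion: all inputs must share one namespace.
- Signaling (non-metabolic) pathway structures are out of scope; the
  reconstruction targets enzyme/compound metabolic topology.
- No overlap pruning between subpathways of the same pathway; heavily
  overlapping significant subregions are reported separately.
- Significance is purely hypergeometric; no permutation or
  topology-weighted null is provided.
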