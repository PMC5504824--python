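# Methods

## Model and assumptions

`isips` treats the interactome as an unweighted, undirected simple graph:
proteins are nodes, physical interactions are edges. The working
hypothesis is that subunits belonging to the same assembly intermediate
share more interaction partners with each other than with the remaining
subunits, so that subcomplexes appear as groups of subunits with strongly
overlapping neighborhoods. Three consequences shape the design:

* **Only external partners count.** Edges among subunits of the complex
  are kept in the graph (they are real interactions) but are subtracted
  from every similarity computation. Intra-complex contacts are exactly
  what we are trying to infer the order of; using them as evidence would
  be circular.
* **The network is complex-centric.** Only records touching at least one
  subunit are retained, so every non-subunit node is a neighbor of some
  subunit. Interactions between two non-subunit proteins never enter.
* **Multiplicity never weights anything.** All set sizes are computed on
  the non-redundant pair table. The number of supporting publications is
  reported (as a reliability hint in the non-redundant tier) but unused.

## Input handling

MITAB rows are parsed positionally (columns 1–2 identifiers, 9
publications, 10–11 taxa, 13 source database, all 1-based; the
`irefindex`, `biogrid`, `intact` and `generic` dialects currently share
these positions). Identifier (`uniprotkb:`), taxon (`taxid:`) and
publication (`pubmed:`) prefixes are stripped; rows with unparseable
identifiers are skipped and counted in the log. Pair identity is the
unordered pair of exact accession strings — no isoform or gene-name
resolution is attempted, which keeps every downstream count auditable.

Filtering drops self-interactions, rows whose two taxon fields differ,
and rows touching no subunit. Records without taxon fields (predictions)
pass the taxon filter: absent taxa compare equal. Scored predictions are
kept when score **strictly** exceeds the cutoff (default 0.5); a cutoff
of 0 therefore disables prediction filtering.

Three nested tiers are written: *full* (every surviving record, input
order), *partially redundant* (within a pair, records contributing no new
PubMed ID are collapsed), and *non-redundant* (one row per unordered
pair, sorted lexicographically, with the count of distinct supporting
PubMed IDs; 0 for prediction-only pairs). Sorting the non-redundant tier
and merging its source labels makes it — and everything computed from
it — invariant under permutation of the input rows.

## Similarity and distance

For disjoint member sets x, y the contingency counts are taken on the
union of member neighborhoods, with members of both clusters excluded
from each side, and split into external (non-subunit) and subunit parts.
With a = shared external interactors, b and c the external interactors
private to each side, and u = a + b + c:

| method         | similarity                    |
|----------------|-------------------------------|
| pseudo_jaccard | a / u                         |
| dice           | 2a / (2a + b + c)             |
| ms             | min(a/(a+b), a/(a+c))         |
| ochiai         | a / √((a+b)(a+c))             |
| overlap        | a / min(a+b, a+c)             |
| kulczynski     | (a/(a+b) + a/(a+c)) / 2       |

Distance is 1 − similarity. All six are symmetric and lie in [0, 1].
Dice and Minimum Sensitivity are the classical alternatives; Ochiai,
Overlap and Kulczynski were chosen to span the geometric-mean,
min-denominator and arithmetic-mean families of 2×2 association measures.
A degenerate denominator (no external interactors on one or both sides)
yields similarity 0, i.e. distance 1, with a logged warning: an
uninformative neighborhood carries no evidence of co-assembly, so such
subunits aggregate last rather than first. Isolated subunits stay in the
analysis with empty interactor sets for the same reason.

## Clustering

Bottom-up agglomeration: start from singletons, repeatedly merge the
pair of clusters at minimal distance, and recompute the distances of the
merged cluster to all others **from the network** (the merged cluster's
interactor set is the union of its members' neighborhoods). Because
distances are recomputed rather than linkage-updated, merge heights can
decrease between steps; no consumer assumes ultrametricity. Ties in the
minimum are broken by the lexicographically smallest sorted-member-tuple
pair, making the trace deterministic and independent of the subunit
input order. Clustering always runs to a single root; there is no
distance threshold or early stopping. Every step records the merged
pair, its distance and the full post-merge matrix; the step-matrices
file round-trips through its own parser.

## Tree, supports, reports

The trace becomes a rooted binary dendrogram; within each merge the
earlier-formed cluster is written first, so the linear format reads
left-to-right in order of formation, e.g.
`((A,B):0.571429,(D,(C,E):0.750000):0.833333):0.916667`.

Each internal node is the branch separating the two leaf sets A and B it
joins. Its support is the rate of well-designed triples: the fraction of
{x, y, y′} with x in one set and y, y′ in the other such that
j(y, y′) ≥ max(j(x, y), j(x, y′)), using the leaf-level similarity
matrix. Ties count as well-designed. A node joining two singletons
admits no triple; its support is 1.0 by convention (absence of
counter-evidence) and the case is logged implicitly by the formula. On a
similarity matrix perfectly nested with the topology every support is 1,
because two elements drawn from one side always look at least as similar
as either does to the outsider. (Supports are defined on the two clades
a node joins, not on a clade versus its complement: two complement-side
leaves that meet only at the root are legitimately dissimilar, and a
complement-based rate could not reach 1 even on perfectly nested input.)

Newick export carries either merge distances (leaves at 0 — only
separating branches have a height) or supports (internal nodes only) as
branch values. The SVG dendrogram is drawn horizontally, root left; the
vertical leaf order is a layout artifact and must not be read as a
chronological ordering.

Interactor reports list, per subcomplex of the trace, the external
proteins touching at least two members (default) or all members, sorted
by member-touch count then ID. For a two-member subcomplex the two modes
coincide, and the all-members list length equals the shared-external
term a of that pair's similarity — a cross-module consistency check the
tests exercise.

## Synthetic data

`synthgen` plants the structure the method assumes. Each module of
subunits gets `shared_within` hub proteins connected to all of its
members; each pair of modules gets `shared_cross` bridge proteins
connected to one (seeded-random) subunit per module; each subunit gets
`private_per_subunit` private partners; each remaining subunit–protein
non-edge is added with probability `noise_edge_prob`. Defaults — two
modules of three subunits, 10/1/2 interactors, 5% noise — are the
benchmark conditions used by the tests: with them, within-module pairs
share ≥ 10 interactors on unions of ~14–15 while cross-module pairs
share at most a bridge plus noise, so the planted split is recovered at
the 2-cluster level in essentially every seeded run (the acceptance
suite requires ≥ 95/100). Files include duplicate rows (same pair and
PubMed ID) and self-interactions so the redundancy tiers and filters are
exercised end-to-end; generation is byte-deterministic given the seed.

What the generator does **not** emulate: scale-free degree
distributions, study bias (hub proteins attracting spurious records),
heterogeneous detection methods, or missing stable interactions. Passing
the planted-recovery benchmark therefore shows the pipeline recovers the
signal it is designed for, not that real interactomes always carry that
signal cleanly; on real data, sparse or promiscuous subunits remain the
main failure mode.

The packaged worked example (5 subunits, 12 external proteins, 24 edges)
is a frozen network realizing the canonical hand-checked contingency
counts (6, 10, 3, 3) for its (A, B) pair — distance 4/7, unique matrix
minimum, first merge — with Dice decomposition a=3, b=1, c=3 (distance
0.4). The exact drawing it imitates was never published as an edge list;
any network with these counts is equivalent for verification purposes.

## Numerical and format choices

* Distances are printed with 6 decimals everywhere; comparisons in tests
  use 1e-12 absolute tolerance on exact rationals.
* Matrix diagonals are stored as 0 and never consulted.
* Output TSVs are tab-separated with header rows; pairs within a row are
  lexicographically ordered.
* Problem sizes in the test and acceptance runs (≤ 8 subunits / ≤ 30
  external proteins for oracle comparisons, 100 seeds for recovery) were
  chosen so that exhaustive brute-force verification stays trivial; the
  pipeline itself handles complexes of tens of subunits and networks of
  hundreds of proteins without special handling.

## Known limitations

* No identifier mapping: records naming the same protein by different
  accessions are treated as different proteins.
* Confidence scores (beyond the prediction cutoff) and publication
  counts never weight the similarity; stability information about
  intra-complex contacts is deliberately unused.
* Transient interactions are under-represented in curated interactomes,
  biasing results toward stable subcomplexes.
* The method needs every subunit to have at least one shared external
  partner to be informative; otherwise the subunit joins the tree last
  at distance 1 (and the pipeline aborts with advice to add predicted
  interactions when *no* subunit has any partner).
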