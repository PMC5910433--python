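# Methods

This note records the models, conventions, and numerical choices behind
each stage of the pipeline, the design decisions taken where several
defensible options existed, and what the synthetic-data tests do and do
not demonstrate about real data.

## Similarity graph and Markov clustering

The similarity weight of an unordered protein pair is the mean, over the
available hit directions, of `bitscore * (qcov + scov) / 2`, with
`qcov = alignment_length / qlen` and `scov = alignment_length / slen`
clamped to [0, 1]. This combines the two ingredients that matter for
family clustering — alignment strength and mutual coverage — and is
isolated in a single function (`clustering.edge_weight`) so an alternative
metric can be swapped in. Merging bidirectional hits by their mean (rather
than max, or keeping a directed matrix) is this package's documented
choice; when several HSPs exist for a directed pair, the highest-bitscore
one is used. Hits with E-value above 10 (the permissive BLAST default) and
self-hits are discarded; proteins without surviving hits remain as
isolated nodes and become singleton clusters.

MCL is implemented directly (dense matrices; the intended scale is
thousands of proteins, not millions): self-loops with weight equal to the
maximum incident edge weight (1 for isolated nodes) prevent dense rows
from swamping sparse ones; columns are normalized; expansion (matrix
squaring) alternates with inflation (entrywise power, renormalization)
until the largest entry change drops below `tol = 1e-6` or `max_iter =
200` rounds, pruning entries below `1e-8` each round. Non-convergence is
reported with a warning and a flag on the result, never silently. Clusters
are the connected components of the non-zero structure of the attractor
matrix; ids are deterministic (size-descending, ties by smallest member
label). Inflation defaults to 2.0, the conventional granularity for
protein families; raising it never decreased the cluster count on the
planted-partition fixture (checked at 1.2 / 2.0 / 4.0).

## Single-copy supermatrix

Phylogenomic markers are clusters with exactly one protein in every
represented species and at least 25 represented species (both
parameters exposed). Alignment trimming is a strict drop-every-gapped-
column filter — the gap policy of "stringent" alignment-trimming tools
without their block-length logic; this is a deliberate simplification, as
alignment computation and trimming are consumed as inputs, not
re-implemented. The 50-column minimum is applied *after* trimming (the
ordering is not dictated by convention; applying it before would keep
alignments whose informative length is lower than the threshold).
Partitions tile the supermatrix exactly and missing species are gap-filled
per partition.

The built-in tree is neighbor joining (scikit-bio) on p-distances
(fraction of differing residues over mutually non-gap columns), midpoint
rooted, with negative NJ branch lengths clamped to zero and species
ordered alphabetically for deterministic tie-breaks. It is a fallback so
the pipeline is self-contained: maximum-likelihood inference is out of
scope, and every downstream stage only needs *a* rooted species tree — a
user-supplied rooted Newick tree takes precedence.

## Reconciliation

LCA mapping is the most-parsimonious reconciliation: `M(leaf)` is the
leaf's species and `M(v)` the species-tree LCA of the children's images.
A node is a duplication iff its image equals a child's image; the edge to
child `c` implies `k − 1` losses at a speciation and `k` at a duplication,
`k` being the species-tree path length from `M(v)` to `M(c)`. Losses
above the gene-tree root are not counted — nothing is known about
pre-root history. An exhaustive sweep (every gene tree with up to 6
leaves against species trees with up to 4 leaves, 21,386 instances)
confirms that these counts equal the brute-force minimum over *all* valid
mappings, for the total cost and for duplications and losses separately.

Unrooted gene trees are rooted at the edge whose rooting minimizes
duplications + losses (unit costs), ties broken by a deterministic
postorder edge order. Statistically informed topology *correction* is not
attempted — gene trees are taken as given; rooting is the one operation
downstream stages cannot do without. Families below four proteins skip
tree inference: one protein is one orthogroup; two proteins form the only
cherry; three proteins get the duplication/loss-cheapest of the three
rooted triplets.

## Orthogroups and Dollo parsimony

Two leaves share an orthogroup exactly when the gene-tree path between
them contains no duplication node; operationally, duplication nodes are
deleted and each leaf-containing component is one orthogroup. The
orthogroup's origin is the species image of its topmost node
(`origin_mode="reconciled"`), so a lineage that originated deep but
survives only in one clade generates losses elsewhere — the
reconciliation-consistent reading. `origin_mode="lca"` restricts the
origin to the LCA of the represented species, which suppresses those
deep-origin losses; both modes are first-class because the choice is a
genuine modeling decision, not a detail.

Dollo parsimony allows one gain and any number of losses: a species-tree
node is present iff it is at-or-below the gain and its subtree retains a
represented species; losses sit on present→absent edges. This placement
is provably minimal and is verified exhaustively against enumeration of
all loss-edge subsets on trees up to 6 leaves. Within an orthogroup a
species may occur repeatedly (hidden paralogy); presence is binary
regardless, since Dollo operates on presence/absence.

Per-branch tallies report orthogroup gains, duplication *nodes* (by their
species image), and Dollo loss edges separately — "duplications" in the
gain-of-orthogroups sense and in the duplication-node sense differ, and
reporting both lets either convention be read off. Ancestral genome size
is the number of orthogroups present at a node, i.e. gene content in
orthogroup units. The bookkeeping identity — for every leaf, root-path
gains minus root-path losses equals the leaf's orthogroup count — is
asserted on every tally, not only in tests.

## Statistics

*Enrichment.* Raw p is the hypergeometric upper tail P(X ≥ k) (scipy);
Bonferroni multiplies by the number of terms with at least one population
carrier — untestable terms cannot be corrected for. The natural unit is
the *cluster* (carrying the union of its members' terms, counted once);
protein-level testing is the same function applied to a protein-level
term map. Type-I behavior is conservative because the statistic is
discrete; the null simulations in the test suite confirm rejection rates
below nominal α within Monte-Carlo error.

*Fisher's exact test* (two-sided, probability-mass rule) comes from
scipy; the test suite verifies it against full enumeration of all tables
with grand total ≤ 12.

*SSP filter.* "Small secreted protein" is read as a protein with a
predicted signal peptide and a whole-protein length of 80–300 aa
inclusive: signal peptides themselves are ~15–30 aa, so the length window
must describe the mature protein, and the boundary values are included.
Proteome fractions are reported to 0.1% and presence screens as integer
percentages, both rounded half-up, matching how such tallies are
conventionally reported.

*Copy-number PCA* centers family columns and decomposes by SVD; variance
fractions are σ²ᵢ over the sum across all components. Covariance
(unscaled) PCA is the default, correlation PCA sits behind `scale=True`
(constant columns are dropped there, since they have no correlation
scale); both are provided because published analyses rarely state the
convention. The sign of each component is fixed by making its
largest-magnitude loading positive; a fully constant matrix is an
explicit error.

## Synthetic data: what it emulates, and what it does not

The species-tree generator is a pure-birth (Yule) process with unit birth
rate — any rooted binary tree with positive branch lengths suffices as a
coordinate system, and pure birth is the simplest process with
controllable depth. Gene families evolve as independent per-lineage
birth–death processes along each branch (exponential waiting times;
duplication splits a lineage, loss ends it); the returned gene tree is the
genealogy of surviving leaves, while the truth record keeps *every* event,
including those erased by extinction. Fully extinct families are emitted
with a flag rather than dropped, so downstream code must handle absence.
No empirical duplication/loss rates are implied by the defaults
(dup 0.5, loss 0.2 per lineage per unit time on a tree of height ≈ 1–2);
they are parameters chosen to produce a few events per family at desk
scale, not estimates of any organism's rates.

The hit-table generator gives every ordered within-family pair a
high-bitscore, near-full-coverage hit (Normal(500, 50) bitscore) and each
between-family pair a weak, partial-coverage hit with probability
`noise_prob` (Normal(40, 8)); E-values are a fixed monotone transform of
the bitscore (halving per 4 score units), because only the ordering and
cutoff behavior matter downstream. The annotation generator plants a term
in chosen clusters, sprinkles it at a background rate elsewhere, and adds
a pool of decoy terms so the Bonferroni factor is non-trivial.

What passing these tests shows: the algorithms are exact (oracle
equivalence), bookkeeping is conserved, and the pipeline recovers planted
structure when the signal matches the generator's assumptions. What they
do not show: robustness to alignment error, gene-tree estimation error,
rate heterogeneity across lineages or families, homology detection
failure, or annotation noise that is structured rather than uniform —
real proteomes violate all of these to some degree. Sequence-level
evolution is deliberately not simulated.

A known property of the event mapping, visible in the simulation tests:
parsimony places an event at the *lowest* branch consistent with the
surviving evidence, so when extinction hides part of a duplication's
descendants the inferred duplication lands below the true branch, and the
orthogroup decomposition scores the parent orthogroup as absent in a
duplicated lineage, creating loss calls with no corresponding simulated
loss event. Aggregate duplication counts are therefore conservative
(never above truth in total), but per-branch counts are not bounded by
per-branch truth — the faithful statement is the path-cumulative bound
asserted in the property suite.

## Problem sizes

The verification runs use 8-taxon trees with 200 families for simulation
recovery, 200 proteins in 10 planted families for clustering, 1,000 null
draws and 100 planted-term runs for the enrichment checks, and the
exhaustive oracle sweeps described above (21,386 reconciliation and 521
Dollo instances) — sizes chosen so the full suite completes in well under
a minute while still exercising every code path at meaningful depth.
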