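# Methods

## Tree model

Every tree is rooted, oriented downwards, and carries an auxiliary
*superroot* above its root; the superroot's edge is the root edge (root
tube for a species tree).  Edges of the species tree are called tubes and
are identified by their lower vertex, so the root tube is named by the
root and every non-superroot vertex names exactly one tube.  The natural
order on the united set of vertices and tubes places the tube into a
vertex strictly between that vertex and its parent.  Species trees are
binary with pairwise-distinct leaf labels; gene trees may be polytomous
and may repeat species (in-paralogs), with leaf labels `id@species`
(species = text after the last `@`; `@` is Newick-safe where underscores
are not).  Newick reading and writing go through dendropy; branch lengths
are parsed and ignored; subdivision and outgroup vertices are suppressed
on output.

## Canonical reconciliation

The canonical mapping α sends the superroot to the root tube, each gene
leaf to its species leaf, and an internal vertex g to LCA(g) unless some
child has the same LCA, in which case g goes into the tube above LCA(g)
(a duplication).  Divergence = vertex mapped onto a species vertex;
loss = ⟨edge e, species vertex s⟩ with image(e_lower) < s <
image(e_upper), implicit when the off-path child clade of s contains no
species of the whole gene tree (not just of the subtree under e — the
choice matters and follows the event definitions).  α is the global
cost minimum whenever divergence costs less than duplication; the test
suite verifies minimality and the dominance property (every other mapping
has at least as many duplications and strictly more losses) against an
exhaustive enumeration of all valid mappings on instances with up to ~10
combined leaves.

## Event costs

`EventCosts` defaults: divergence 0, duplication 2, explicit loss 1,
implicit loss 0, transfer (with or without retention) 3, gain 2.
Divergence and implicit loss are free because the zero-cost supertree
theorem presupposes exactly that (a tree that perfectly explains its
pruned gene trees should cost nothing); duplication > loss and
transfer > duplication follow the classic DTL weighting in which rarer
events cost more.  Any cost may be set to `inf` to forbid the event; the
cost accumulator skips zero-count terms so forbidden-but-absent events do
not poison totals.

## Time slices and the scenario DP

`assign_time_slices` implements the uniform-depth policy: single-child
subdivision vertices pad every root-to-leaf path to the same tube count
h, the rank of a tube is its depth index, leaf tubes share rank h−1, and
every rank is a full cut of the tree, so "same rank" means
"contemporaries".  Other ranking policies would be admissible (the only
requirement is that lower tubes never get a smaller rank) but only
uniform depth is provided.

The DP fills cost(e, d) for every gene edge e and tube d, visiting gene
edges leaf-to-root and tubes by decreasing rank, so every referenced pair
is already computed.  The base case pairs a leaf edge with a leaf tube
(0 for the gene's own species tube, one transfer without retention
otherwise — all leaf tubes share a slice under the default policy, so
these transfers are slice-legal).  The induction rules cover: descending
a subdivision tube; surviving in one child tube with a loss in the other;
duplicating inside d; diverging at d's lower vertex; duplicating with a
transfer-with-retention into d′ ~ d; and a transfer-without-retention
into d′ followed by a descent, loss, duplication, divergence, or a second
(retained) transfer into d″ ~ d′ (the donor-copy loss of that family of
rules is not separately costed, matching the cost recursion as stated).
Gain mode attaches a chain of outgroup tubes, one per slice, beside the
root tube; entry into the chain at the root is free, losses at the root
tube and duplications inside the chain are free, transfers leaving the
chain cost `gain` instead of a transfer, and transfers may never target
the chain.

Tie-breaking is deterministic with rule precedence divergence < loss <
descend < duplicate < gain-split < transfer rules, and lexicographically
smallest d′/d″ within a rule.  Descend-before-duplicate is what makes the
transfer-free scenario coincide with α *including event locations*: a
cost-tied duplication is pushed down to the tube above the LCA, exactly
where α puts it.  Backtracking inserts single-child vertices only for
transfers — two per transfer without retention (donor and recipient
positions), one per transfer with retention — so n insertions on an edge
decode as n/2 transfers without retention (n even) or one with retention
plus (n−1)/2 without (n odd).

A memoization-free recursive enumerator of all inner trees serves as the
independent oracle; the DP equals it on every tested instance and cost
vector.  Table size is |edges(G)| × |tubes|, and per-entry work is
quadratic in the slice width, giving the cubic-in-species-tree bound; the
tests check the operation-count trend on a doubling ladder rather than
wall-clock time.

## Supertree phases

Phase 1 enumerates the clade family P by increasing cardinality.
Singletons are always basic, with base cost c_dup · Σ_j Par(G_j, s)
(Par = internal vertices of maximal single-species subtrees); the base
constants only shift all costs and never change the optimal topology,
which the tests confirm.  A larger member is basic when some partition
into two basic members of P (or singletons) exists; its cost adds the
q-count join term to the halves' costs.  The q-counts run over the gene
trees: q1 counts vertices whose child clades split across the halves
(divergences at the join root), q2 counts vertices inside V whose child
clade touches both halves (duplications in the join's root tube), and
q3′/q3″ count edges whose lower clade sits inside one half while the
upper end maps strictly above the join (sibling clade in neither half,
or the superroot), split explicit/implicit by whether the tree touches
both halves or one.  The superroot vertex itself is never counted toward
q1/q2 (it is not an event); its edge does participate in q3.  Ties among
equal-cost partitions go to the lexicographically smallest sorted pair.
With P the full powerset the Phase-1 optimum equals an exhaustive search
over all (2n−3)!! rooted species trees, which the tests verify directly.

Phase 2 scores a candidate tree by the total α-cost of every basic tree
(≥ 2 leaves) pruned to the candidate's species set and mapped into it.
The base step picks the best 3-species topology, the augmentation step
the best (species, edge) insertion, both by c · (2 − R) with reliability
R = (c′ − c)/c′ where c′ is the smallest cost strictly above c; a
species with no defined c′ is marked unreliable and left out; all
remaining ties break lexicographically.  The root edge counts as an
insertion site.  The modified Phase 1 repeats the recursion on instances
pruned to each member of P and feeds those per-clade trees to Phase 2;
basicness survives pruning, which the tests check.

**Consistency condition for the zero-cost outcome.**  The zero-cost
theorem promises a zero-cost supertree only when every basic tree is a
pruning of one reference tree.  Randomly pruned gene trees do not
guarantee this: a draw can leave some reference split with no witnessing
clade, so the compatible partition of V0 is missing from P and the forced
alternative conflicts with the reference.  The fixture generator
(`pruned_gene_trees`) therefore rejection-samples prunings until the gene
trees jointly contain every split of the reference as a clade; under that
condition the zero-cost outcome is exact in every tested seed.

## Polytomy machinery

An edge enters a tube d when d(e_upper) is strictly above d and d is
weakly above d(e_lower), with d(g) the α-image as a tube.  Bundles group
a tube's entering edges by upper terminus; p(G, d) = number of bundles is
the per-tube lower bound on entering edges over all candidate
binarizations, attained by the paralogous binarization G##.  The
construction resolves each polytomous vertex by the three-part child
split (stay in d(g) / below d1 / below d2), separating the first part
from the rest, and splitting a lone first part first-child-versus-rest
(any split of it is cost-equivalent).  The implementation recomputes α
per resolution step for clarity — quadratic worst case rather than the
linear bound, irrelevant at practical polytomy sizes.

Per-tube minimality alone does **not** pin the embedding cost: a
candidate can match every per-tube minimum while pairing entering edges
of sibling tubes under different upper termini, trading divergences for
duplications and extra losses.  The cost-invariant class — what the
construction actually produces — additionally realizes the shared-parent
bundle pairing (entering edges of sibling tubes share an upper terminus
exactly when the bundles share their parent vertex).
`is_paralogous_binarization` tests both conditions, and the invariance
property is asserted over that class by exhaustive candidate enumeration.

The polytomous Phase 1 replaces the q-count join term with bundle
counts: k shared-parent bundle pairs are divergences, n1 + n2 − n − k
duplications, n1 + n2 − 2k losses (split explicit/implicit per tree as
before), where n, n1, n2 count bundles for the conceptual tubes above
and into the halves, read off clades alone; the superroot edge counts as
entering the join tube when its clade lies inside V (this convention is
forced by the duplication count and by exact agreement with the binary
recursion on binary inputs, which the tests assert).  The singleton base
uses Par′(G, s) = (leaves under the leaf tube's bundles) − (bundle
count), the duplication count any paralogous binarization places in that
leaf tube.  The optimal (unconstrained) binarization is intentionally not
an algorithm here — only an exhaustive oracle at test scale — since the
paralogous class is the biologically motivated and tractable target.

## Synthetic data

The forward simulator is a discrete, slice-aligned stand-in for a
continuous birth–death-transfer process: per (lineage, tube) one decision
— loss (p_los), duplication (p_dup), transfer with retention to a uniform
same-slice tube (p_tr), else nothing — with divergence forced at species
vertices.  Defaults p_dup = p_los = 0.05, p_tr = 0.02 keep roughly one
event per family on a 6-taxon tree, the regime where parsimony is
expected to recover the history.  Extinct lineages are pruned; recorded
ground truth keeps only events visible in the surviving tree (a transfer
whose donor copy died is recorded as transfer-without-retention; events
with a single surviving side vanish).  What passing tests show is
therefore recovery of *visible* discrete events at low rates — not
statistical performance on clock-like data with rate heterogeneity,
which the generator does not emulate.  All randomness flows from one
integer seed through numpy generators; every operation is deterministic
per seed.

## Numerical and degenerate-input choices

Costs are floats; all oracle comparisons are exact-zero or 1e-9-tolerance
on sums of at most dozens of terms.  `inf` costs propagate through the DP
and are reported as "no feasible scenario".  Single-leaf gene trees are
valid scenario inputs; the empty intersection in pruning, duplicate
species labels, unknown species in gene leaves, nonbinary species trees,
and polytomous gene trees in the scenario DP are rejected with named
errors.  Phase 2 requires at least three species; smaller instances are
answered by Phase 1 alone.

## Problem sizes used in the shipped checks

The exhaustive oracles run on: mappings — all (G, S) with up to 4 leaves
each plus 200 random 5-leaf pairs; scenarios — all listed (G, S) with up
to 3 leaves each under 5 random cost vectors, plus 100 random ≤6-leaf
reductions; supertrees — 50 random instances with |V0| ≤ 5 against all
(2n−3)!! topologies; binarizations — full candidate enumeration for ≤6
leaf polytomies.  These sizes make every oracle comparison exact while
keeping the whole suite in seconds.

## Known limitations

Unrooted trees, branch-length dating, per-edge reliability weights,
probabilistic/coalescent reconciliation, species-tree-side polytomies and
the unconditional (NP-complete) supertree search are out of scope.  The
conditional supertree is exact only relative to the clade family P; with
transfers the supertree problem is not addressed at all.  Phase 2 remains
a heuristic whenever V0 is not basic and its hypothesis fails; the
package reports such outcomes rather than forcing a tree.
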