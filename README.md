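# treerec

Event-based reconciliation of gene trees with species trees, for
phylogenomics workflows that need to explain gene-family histories through
duplications, losses, horizontal transfers and gains, or to assemble many
gene trees into one species supertree.

## What it computes

**Canonical reconciliation (α).**  For a rooted gene tree *G* and a rooted
binary species tree *S*, the canonical mapping sends a gene vertex *g* to
LCA(*g*) — the last common ancestor in *S* of the species below *g* — when
every child of *g* has a strictly smaller LCA, and otherwise into the
*tube* (species-tree edge) just above LCA(*g*), which marks a duplication.
Divergences are gene vertices mapped onto species vertices; a loss is a
pair ⟨*e*, *s*⟩ of a gene edge and a species vertex strictly between the
images of the edge's endpoints, *implicit* when the pruned side carries no
species present in *G* and *explicit* otherwise.  Whenever a divergence
costs less than a duplication, α is the global minimum of the event cost
over all valid mappings — the package ships an exhaustive-mapping oracle
that verifies this on small instances.

**DTL scenarios on a time-sliced species tree.**  Tubes are ranked into
time slices (lower tubes never get a smaller rank); transfers are legal
only between distinct tubes of one slice.  A dynamic program over pairs
⟨gene edge *e*, tube *d*⟩ builds the cheapest *inner tree* — an
alternative evolution of *e* inside *d* — under duplication, loss,
divergence, transfer with/without retention of the donor copy, and
(optionally) gene gain through an auxiliary outgroup chain.  The optimum
at the root pair is the scenario cost; backtracking yields the event list
and the gene tree with transfer points inserted.  With transfers forbidden
the scenario coincides exactly with α, events included.

**Conditional supertrees.**  Given gene trees {*G<sub>j</sub>*} and a
clade family *P* (defaulting to all gene-tree clades, singletons, and the
full species set *V*₀), Phase 1 computes, for every *basic* set
*V* ∈ *P* (partitionable within *P* down to singletons), the
minimum-cost tree *S*(*V*) by the recursion

```
c(V, V1, V2) = c(V1) + c(V2) + c_div·q1 + c_dup·q2 + c_los1·q3' + c_los2·q3''
```

whose q-counts read the divergences, duplications and explicit/implicit
losses at the join of *V*₁ and *V*₂ directly off the gene trees.  If *V*₀
is basic, *S*(*V*₀) is the exact conditional optimum.  Phase 2 assembles
basic trees into a supertree by reliability-weighted augmentation (score
c·(2−R), R = (c′−c)/c′): when every basic tree is a pruning of one
reference tree and implicit losses and divergences are free, the result
has cost exactly zero.  A modified Phase 1 re-runs the recursion on
per-clade pruned instances for more accurate Phase-2 input.

**Polytomy resolution.**  A polytomous gene tree is resolved into a
*paralogous binarization* G<sup>##</sup> which, per tube, realizes the
minimal number of entering gene edges (one per *bundle* — a maximal
same-parent set of edges entering the tube).  The bundle counts also give
the polytomous Phase-1 recursion, so supertrees can be built from
unresolved gene trees without materializing binarizations.

## Worked example

Reconcile a conflicting gene tree `((a,c),b)` with the species tree
`((a,b),c)`:

```sh
$ printf '((a,c),b);' > gene.nwk
$ printf '((a,b),c);' > species.nwk
$ treerec alpha --gene gene.nwk --species species.nwk
event_type	gene_vertex	species_location	explicit
duplication	0	tube:0	
divergence	1	vertex:0	
loss	4	vertex:1	1
loss	4	vertex:0	1
loss	2	vertex:1	1
total cost: 5.0
```

The gene root is a duplication in the root tube, the `(a,c)` vertex
diverges at the species root, and three explicit losses are charged along
the paths of the copies; at the default costs (duplication 2, explicit
loss 1, divergence and implicit loss 0) the total is 5.  The scenario
engine can trade those losses for a transfer instead:

```sh
$ treerec scenario --gene gene.nwk --species species.nwk
total cost: 4.0
```

(a divergence, one transfer at default cost 3 and a single explicit loss
beat the duplication plus three losses).
Library use mirrors the CLI:

```python
from treerec import (parse_newick, compute_alpha, infer_events, EventCosts)
G = parse_newick("((a,c),b);")
S = parse_newick("((a,b),c);", role="species")
inv = infer_events(G, S, compute_alpha(G, S), EventCosts())
print(inv.counts(), inv.total_cost)   # 1 dup, 1 div, 3 explicit losses; 5.0
```

Other subcommands: `treerec supertree --genes g1.nwk g2.nwk ...`
(conditional supertree, `--poly` for polytomous inputs, `--modified` and
`--phase2` for the augmentation variants), `treerec binarize` (paralogous
binarization), and `treerec simulate` (synthetic species/gene trees with
ground-truth events).

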