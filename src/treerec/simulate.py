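"""Synthetic species and gene trees with known ground-truth events.

The forward simulator is a discrete, slice-aligned analog of a birth-death
process with transfers: in every tube each surviving gene lineage makes
one decision (duplicate / die / transfer with retention / nothing) with
fixed probabilities, diverges at every species vertex, and becomes an
observable gene at a species leaf.  Extinct lineages are pruned from the
returned gene tree and the recorded ground truth keeps only events with
surviving descendants on the relevant sides.

The module also hosts the small exhaustive enumerators used as oracles
(every rooted binary topology over a label set) and the consistent-pruning
fixture generator for the zero-cost supertree theorem, which requires the
gene trees to jointly witness every split of the reference tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconcile import EventInventory
from .trees import RootedTree, SlicedSpeciesTree, TreeError, prune_to

__all__ = ["EvolutionRates", "random_species_tree", "evolve_gene_tree",
           "enumerate_rooted_trees", "pruned_gene_trees", "count_topologies"]


@dataclass(frozen=True)
class EvolutionRates:
    """Per-tube per-lineage event probabilities of the forward simulator."""

    p_dup: float = 0.05
    p_los: float = 0.05
    p_tr: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_dup, self.p_los, self.p_tr):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_dup + self.p_los + self.p_tr > 1.0:
            raise ValueError("p_dup + p_los + p_tr must not exceed 1")


def _insert_everywhere(nested, lab):
    out = [[nested, lab]]
    if isinstance(nested, list):
        left, right = nested
        out += [[l, right] for l in _insert_everywhere(left, lab)]
        out += [[left, r] for r in _insert_everywhere(right, lab)]
    return out


def random_species_tree(labels, seed) -> RootedTree:
    """Uniformly random rooted binary topology by sequential leaf
    attachment; deterministic per seed."""
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least two species")
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate species labels")
    rng = np.random.default_rng(seed)
    nested = labels[0]
    for lab in labels[1:]:
        options = _insert_everywhere(nested, lab)
        nested = options[rng.integers(len(options))]
    return RootedTree.from_nested(nested)


def count_topologies(n: int) -> int:
    """(2n-3)!! rooted binary topologies over n labelled leaves."""
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def enumerate_rooted_trees(labels):
    """Every rooted binary topology over the labels, exactly once."""
    labels = sorted(labels)
    if not 2 <= len(labels) <= 6:
        raise TreeError("topology enumeration supports 2..6 labels")
    structs = [labels[0]]
    for lab in labels[1:]:
        structs = [s for t in structs for s in _insert_everywhere(t, lab)]
    return [RootedTree.from_nested(s) for s in structs]


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

class _Lin:
    __slots__ = ("id", "children", "event", "loc", "alive")

    def __init__(self, id, loc):
        self.id = id
        self.children = []
        self.event = None       # ("dup", tube) | ("tr", donor, recip) | ...
        self.loc = loc
        self.alive = True


def evolve_gene_tree(S0: SlicedSpeciesTree, rates: EvolutionRates):
    """Simulate one gene family along the sliced species tree.

    Returns (gene tree, true EventInventory).  Raises ``TreeError`` when
    every lineage goes extinct (caller retries with another seed).
    """
    rng = np.random.default_rng(rates.seed)
    tree = S0.tree
    counter = [0]

    def new_node(loc):
        counter[0] += 1
        return _Lin(counter[0], loc)

    root_lin = new_node(tree.root)

    def simulate(node, tube):
        """Evolve one lineage through ``tube`` and below."""
        u = rng.random()
        if u < rates.p_los:
            node.alive = False
            node.event = ("loss", tube)
            return
        if u < rates.p_los + rates.p_dup:
            # one decision per (lineage, tube): the copies continue
            # downwards without re-deciding inside this tube
            node.event = ("dup", tube)
            for _ in range(2):
                child = new_node(tube)
                node.children.append(child)
                _descend(child, tube)
            return
        if u < rates.p_los + rates.p_dup + rates.p_tr:
            peers = [d for d in S0.tubes()
                     if S0.same_slice(d, tube) and d not in S0.outgroup_tubes]
            if peers:
                recip = peers[rng.integers(len(peers))]
                node.event = ("tr", tube, recip)
                stay, move = new_node(tube), new_node(recip)
                node.children = [stay, move]
                _descend(stay, tube)
                _descend(move, recip)
                return
        _descend(node, tube)

    def _descend(node, tube):
        kids = tree.children[tube]
        if not kids:  # species leaf: observable gene
            node.event = ("leaf", tube)
            return
        if len(kids) == 1:  # subdivision vertex
            simulate_next(node, kids[0])
            return
        node.event = ("div", tube)
        for d in kids:
            child = new_node(d)
            node.children.append(child)
            simulate_next(child, d)

    def simulate_next(node, tube):
        simulate(node, tube)

    simulate(root_lin, tree.root)

    # prune extinct lineages
    def survivors(node):
        if node.event and node.event[0] == "leaf":
            return 1
        n = sum(survivors(c) for c in node.children)
        node.alive = node.alive and n > 0
        return n

    if survivors(root_lin) == 0:
        raise TreeError("all lineages extinct; retry with another seed")

    inv = EventInventory()
    gene_counter = [0]

    def build(node):
        """Observable nested structure below node, recording visible
        events (those with surviving witnesses on the relevant sides)."""
        if node.event and node.event[0] == "leaf":
            gene_counter[0] += 1
            return f"g{gene_counter[0]}@{tree.species_of(node.event[1])}"
        parts = [(c, build(c)) for c in node.children]
        live = [(c, p) for c, p in parts if p is not None]
        if not live:
            return None
        kind = node.event[0]
        if len(live) == 2:
            if kind == "dup":
                inv.duplications.append((node.id, node.event[1]))
            elif kind == "tr":
                inv.transfers.append((node.id, node.event[1],
                                      node.event[2], True))
            elif kind == "div":
                inv.divergences.append((node.id, node.event[1]))
            return [p for _, p in live]
        # one surviving side: the event is invisible, except a transfer
        # whose only survivor is the moved copy (seen as no-retention)
        if kind == "tr" and live[0][0] is node.children[1]:
            inv.transfers.append((node.id, node.event[1],
                                  node.event[2], False))
        return live[0][1]

    nested = build(root_lin)
    if isinstance(nested, str):
        gene = RootedTree.from_nested(nested)
    else:
        gene = RootedTree.from_nested(nested)
    return gene, inv


# ---------------------------------------------------------------------------
# consistent prunings (zero-cost supertree fixtures)
# ---------------------------------------------------------------------------

def _splits(ref: RootedTree):
    out = set()
    for v in ref.children:
        if v == ref.superroot or ref.is_leaf(v):
            continue
        for c in ref.children[v]:
            cl = ref.clade(c)
            if len(cl) > 1:
                out.add(cl)
    return out


def pruned_gene_trees(ref: RootedTree, n: int, seed,
                      require_cover: bool = True, max_tries: int = 500):
    """Derive n gene trees from the reference by pruning one random proper
    subtree each.

    With ``require_cover`` (the default) the draw is rejected until the
    gene trees jointly contain every split of the reference as a clade --
    the consistency condition under which the zero-cost supertree theorem
    applies (every basic tree is then a pruning of the reference).
    """
    rng = np.random.default_rng(seed)
    full = ref.clade(ref.root)
    cands = sorted(v for v in ref.children
                   if v not in (ref.superroot, ref.root)
                   and len(full - ref.clade(v)) >= 2)
    if not cands:
        raise TreeError("reference tree too small to prune")
    need = _splits(ref)
    for _ in range(max_tries):
        trees = []
        for _ in range(n):
            v = cands[rng.integers(len(cands))]
            trees.append(prune_to(ref, full - ref.clade(v)))
        if not require_cover:
            return trees
        have = {g.clade(v) for g in trees
                for v in g.children if v != g.superroot}
        if need <= have:
            return trees
    raise TreeError("no consistent pruning draw found; supply more gene "
                    "trees or a larger reference")
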