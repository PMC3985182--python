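"""Duplication/loss reconciliation: the canonical LCA mapping, mapping
validation, event inference and costing, and an exhaustive-mapping oracle.

A *mapping* assigns every gene-tree vertex to a vertex or tube of the
species tree: the superroot goes to the root tube, each gene leaf to the
species leaf of its species, children map weakly below their parent, and a
vertex mapped onto a species vertex must send its children into distinct
child subtrees.  The canonical mapping alpha sends a gene vertex g to
LCA(clade(g)) when every child has a strictly smaller LCA, and to the tube
above that LCA otherwise (a duplication).  When a divergence costs less
than a duplication, alpha is the global cost minimum over all mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import (RootedTree, TreeError, loc_strict_less, loc_weak_leq)

__all__ = [
    "EventCosts", "Mapping", "EventInventory",
    "compute_alpha", "validate_mapping", "infer_events", "event_cost",
    "enumerate_mappings", "par_count",
]


@dataclass(frozen=True)
class EventCosts:
    """Per-event-type nonnegative costs; ``inf`` forbids an event.

    The divergence (speciation-congruent split) must cost less than a
    duplication, otherwise the canonical mapping is not guaranteed optimal.
    """

    div: float = 0.0
    dup: float = 2.0
    loss_explicit: float = 1.0
    loss_implicit: float = 0.0
    transfer_ret: float = 3.0
    transfer_norel: float = 3.0
    gain: float = 2.0

    def __post_init__(self):
        for name in ("div", "dup", "loss_explicit", "loss_implicit",
                     "transfer_ret", "transfer_norel", "gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative cost for {name}")

    def check_div_lt_dup(self):
        if not self.div < self.dup:
            raise ValueError("divergence must cost less than duplication")


@dataclass
class Mapping:
    """Gene vertex -> species location table.  A location is ``("v", s)``
    for species vertex s or ``("t", s)`` for the tube entering s."""

    target_of: dict

    def __getitem__(self, g):
        return self.target_of[g]

    def items(self):
        return self.target_of.items()


@dataclass
class EventInventory:
    """Localized events of one reconciliation.

    ``losses`` entries are (gene edge, species vertex, explicit?); a gene
    edge is named by its lower vertex.  ``transfers`` entries are
    (gene edge, donor tube, recipient tube, retention?).
    """

    duplications: list = field(default_factory=list)   # (gene vertex, tube)
    divergences: list = field(default_factory=list)    # (gene vertex, vertex)
    losses: list = field(default_factory=list)         # (edge, vertex, bool)
    transfers: list = field(default_factory=list)      # (edge, d, d', bool)
    gains: list = field(default_factory=list)          # (edge, re-entry tube)
    total_cost: float = 0.0

    def counts(self):
        nle = sum(1 for *_, ex in self.losses if ex)
        return {
            "duplications": len(self.duplications),
            "divergences": len(self.divergences),
            "losses_explicit": nle,
            "losses_implicit": len(self.losses) - nle,
            "transfers": len(self.transfers),
            "gains": len(self.gains),
        }

    def dl_multiset(self):
        """Order-free content of the duplication/loss/divergence events,
        for comparing two inventories over the same trees."""
        return (frozenset(self.duplications), frozenset(self.divergences),
                frozenset((e, s, x) for e, s, x in self.losses))


def event_cost(inv: EventInventory, costs: EventCosts) -> float:
    """Weighted sum of the inventory under ``costs``; +inf propagates."""
    c = inv.counts()
    total = 0.0
    for n, w in ((c["duplications"], costs.dup),
                 (c["divergences"], costs.div),
                 (c["losses_explicit"], costs.loss_explicit),
                 (c["losses_implicit"], costs.loss_implicit),
                 (c["gains"], costs.gain)):
        if n:  # avoid inf * 0 for forbidden-but-absent events
            total += w * n
    for *_, ret in inv.transfers:
        total += costs.transfer_ret if ret else costs.transfer_norel
    return total


# ---------------------------------------------------------------------------
# canonical mapping
# ---------------------------------------------------------------------------

def _species_leaf_table(S: RootedTree):
    return {S.species_of(l): l for l in S.labels}


def compute_alpha(G: RootedTree, S: RootedTree) -> Mapping:
    """The canonical (LCA) mapping of G into S.

    Works for polytomous G with the "for all children" reading: g maps to
    the tube above LCA(g) as soon as any child shares its LCA.
    """
    leaf_of = _species_leaf_table(S)
    for l in G.labels:
        if G.species_of(l) not in leaf_of:
            raise TreeError(
                f"gene leaf {G.labels[l]!r}: species {G.species_of(l)!r} "
                f"absent from the species tree")
    lca = {}
    target = {G.superroot: ("t", S.root)}
    for g in G.postorder():
        if g == G.superroot:
            continue
        if G.is_leaf(g):
            lca[g] = leaf_of[G.species_of(g)]
            target[g] = ("v", lca[g])
        else:
            node = lca[G.children[g][0]]
            for c in G.children[g][1:]:
                a, b = node, lca[c]
                while a != b:
                    if S.depth(a) >= S.depth(b):
                        a = S.parent[a]
                    else:
                        b = S.parent[b]
                node = a
            lca[g] = node
            if any(lca[c] == node for c in G.children[g]):
                target[g] = ("t", node)
            else:
                target[g] = ("v", node)
    return Mapping(target)


def validate_mapping(G: RootedTree, S: RootedTree, f: Mapping):
    """Check the mapping conditions; returns ``None`` when valid, else a
    ``(condition, gene vertex)`` pair naming the first violation."""
    leaf_of = _species_leaf_table(S)
    if f[G.superroot] != ("t", S.root):
        return ("superroot", G.superroot)
    for g in G.postorder():
        if g == G.superroot:
            continue
        t = f[g]
        if G.is_leaf(g):
            if t != ("v", leaf_of.get(G.species_of(g))):
                return ("leaf", g)
            continue
        kids = [f[c] for c in G.children[g]]
        if not all(loc_weak_leq(S, k, t) for k in kids):
            return ("order", g)
        if t[0] == "v":
            s = t[1]
            sides = []
            for k in kids:
                if not loc_strict_less(S, k, ("v", s)):
                    return ("order", g)
                # a subtree includes its root edge: locate k by lower vertex
                side = next(c for c in S.children[s]
                            if S.is_weak_ancestor(c, k[1]))
                sides.append(side)
            if len(set(sides)) != len(sides):
                return ("divergence side condition", g)
    return None


# ---------------------------------------------------------------------------
# event inference
# ---------------------------------------------------------------------------

def _losses_on_edge(G, S, lower_loc, upper_loc, gene_species):
    """Species vertices strictly between the two locations, with the
    explicit/implicit flag read off the off-path child clades."""
    x = lower_loc[1]
    out = []
    s = S.parent[x]
    while s is not None and loc_strict_less(S, ("v", s), upper_loc):
        explicit = any(S.clade(c) & gene_species
                       for c in S.children[s]
                       if not S.is_weak_ancestor(c, x))
        out.append((s, explicit))
        s = S.parent[s]
    return out


def infer_events(G: RootedTree, S: RootedTree, f: Mapping,
                 costs: EventCosts) -> EventInventory:
    """List every duplication, divergence and loss of the mapping exactly
    once, with its location, and the total cost.

    A loss ``(e, s)`` is charged for every species vertex s strictly
    between the images of the edge's termini; it is implicit when the
    off-path child clade of s contains no species present in G.
    """
    bad = validate_mapping(G, S, f)
    if bad is not None:
        raise TreeError(f"invalid mapping: {bad}")
    gene_species = G.species_set()
    inv = EventInventory()
    for g in G.postorder():
        if g == G.superroot:
            continue
        t = f[g]
        if t[0] == "t":
            inv.duplications.append((g, t[1]))
        elif not G.is_leaf(g):
            inv.divergences.append((g, t[1]))
        for s, explicit in _losses_on_edge(G, S, t, f[G.parent[g]],
                                           gene_species):
            inv.losses.append((g, s, explicit))
    inv.total_cost = event_cost(inv, costs)
    return inv


# ---------------------------------------------------------------------------
# exhaustive-mapping oracle
# ---------------------------------------------------------------------------

def enumerate_mappings(G: RootedTree, S: RootedTree, guard: int = 12):
    """Yield every valid mapping of G into S exactly once (test-scale
    oracle; refuses instances with more than ``guard`` combined leaves)."""
    if len(G.labels) + len(S.labels) > guard:
        raise TreeError("instance too large for exhaustive mapping "
                        "enumeration; oracle is for test scale only")
    leaf_of = _species_leaf_table(S)
    order = [g for g in G.postorder() if g != G.superroot]
    locations = [("v", s) for s in sorted(S.children) if s != S.superroot]
    locations += [("t", s) for s in sorted(S.children) if s != S.superroot]

    def candidates(g, assigned):
        if G.is_leaf(g):
            return [("v", leaf_of[G.species_of(g)])]
        kids = [assigned[c] for c in G.children[g]]
        out = []
        for t in locations:
            if not all(loc_weak_leq(S, k, t) for k in kids):
                continue
            if t[0] == "v":
                s = t[1]
                sides = []
                ok = True
                for k in kids:
                    if not loc_strict_less(S, k, ("v", s)):
                        ok = False
                        break
                    sides.append(next(c for c in S.children[s]
                                      if S.is_weak_ancestor(c, k[1])))
                if not ok or len(set(sides)) != len(sides):
                    continue
            out.append(t)
        return out

    def rec(i, assigned):
        if i == len(order):
            full = dict(assigned)
            full[G.superroot] = ("t", S.root)
            yield Mapping(full)
            return
        g = order[i]
        for t in candidates(g, assigned):
            assigned[g] = t
            yield from rec(i + 1, assigned)
            del assigned[g]

    yield from rec(0, {})


# ---------------------------------------------------------------------------
# paralogous subtrees
# ---------------------------------------------------------------------------

def par_count(G: RootedTree, s: str) -> int:
    """Par(G, s): total nonleaf vertices over all maximal subtrees of G
    whose clade is the singleton {s}; equals the number of duplications the
    canonical mapping locates in the leaf tube of s."""
    singleton = frozenset([s])
    total = 0
    for v in G.children:
        if v == G.superroot or G.clade(v) != singleton:
            continue
        p = G.parent[v]
        if p != G.superroot and G.clade(p) == singleton:
            continue  # not maximal
        total += sum(1 for u in G.preorder(v) if not G.is_leaf(u))
    return total
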