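"""Minimum-cost evolutionary scenario on a time-sliced species tree.

The dynamic program fills a table indexed by pairs (gene edge e, tube d);
the entry is the minimal cost of evolving the gene lineage of e inside d
and below, under duplication, loss, divergence, and horizontal transfer
with or without retention of the donor copy (transfers are legal only
between distinct tubes of one time slice).  An optional auxiliary outgroup
chain models gene gain: a lineage routed through the outgroup and
transferred back into the species tree is a gained gene.

Pairs are visited gene edges leaf-to-root and, within an edge, tubes by
decreasing rank, so every rule refers only to already-filled entries.  The
entry at (root edge, root tube) is the scenario cost; with transfers and
gain forbidden the backtracked scenario coincides with the canonical
mapping and its events.

Rule tags (kept in the choice table for backtracking):

* ``base`` -- leaf edge in a leaf tube; a transfer without retention when
  the tube is not the leaf's own species tube;
* ``1`` -- descend into the single child tube (subdivision vertex);
* ``2`` -- survive in one child tube, loss in the other;
* ``3`` -- duplication inside d; ``3p`` -- free split into the outgroup;
* ``4`` -- divergence at the lower vertex of d;
* ``5`` -- duplication plus transfer with retention into d' ~ d;
* ``6.1``-``6.5`` -- transfer without retention into d' ~ d followed by a
  descent / loss / duplication / divergence / second transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .reconcile import EventCosts, EventInventory, Mapping
from .trees import RootedTree, SlicedSpeciesTree, TreeError

__all__ = ["InnerTreeTable", "Scenario", "build_inner_table",
           "best_scenario", "scenario_report", "enumerate_inner_cost"]

INF = math.inf


@dataclass
class InnerTreeTable:
    """DP product: ``cost_of[(e, d)]`` and the minimizing rule choice."""

    cost_of: dict
    choice_of: dict
    gene_tree: RootedTree
    sliced: SlicedSpeciesTree
    costs: EventCosts
    gain: bool
    n_candidates: int = 0  # rule alternatives evaluated (work proxy)

    @property
    def root_entry(self):
        G, S0 = self.gene_tree, self.sliced
        return self.cost_of[(G.root, S0.tree.root)]


@dataclass
class Scenario:
    """A backtracked minimum-cost scenario.

    ``gene_tree_prime`` is the input gene tree with single-child vertices
    inserted for transfers (two per transfer without retention -- donor and
    recipient positions -- and one per transfer with retention), so on any
    edge carrying n inserted vertices: n even means n/2 transfers without
    retention, n odd means one with retention plus (n-1)/2 without.
    """

    gene_tree_prime: RootedTree
    mapping: Mapping
    events: EventInventory
    total_cost: float


def _loss_flag(S0: SlicedSpeciesTree, tube, gene_species):
    """Explicit iff the subtree below ``tube`` carries a species of G."""
    tree = S0.tree
    return bool(tree.clade(tube) & gene_species)


def build_inner_table(G: RootedTree, S0: SlicedSpeciesTree,
                      costs: EventCosts, gain: bool = False
                      ) -> InnerTreeTable:
    """Fill the (gene edge, tube) cost table in the inductive order."""
    tree = S0.tree
    if gain and not S0.outgroup_tubes:
        raise TreeError("gain requested but the sliced tree has no outgroup "
                        "chain; slice with with_outgroup=True")
    if not G.is_binary:
        raise TreeError("gene tree must be binary; binarize polytomies first")
    species_leaves = {tree.species_of(l): l for l in tree.labels}
    gene_species = G.species_set()
    for l in G.labels:
        if G.species_of(l) not in species_leaves:
            raise TreeError(f"species {G.species_of(l)!r} absent from the "
                            f"species tree")
    outg = S0.outgroup_tubes
    tubes = S0.tubes()  # decreasing rank, deterministic
    d0 = tree.root
    # tubes grouped by slice, ascending vertex id for deterministic d'/d''
    by_rank = {}
    for d in tubes:
        by_rank.setdefault(S0.rank_of[d], []).append(d)
    for lst in by_rank.values():
        lst.sort()

    cost_of, choice_of = {}, {}
    n_candidates = 0

    def c_loss(sub):
        return (costs.loss_explicit if _loss_flag(S0, sub, gene_species)
                else costs.loss_implicit)

    gene_edges = [g for g in G.postorder() if g != G.superroot]
    for e in gene_edges:
        e_leaf = G.is_leaf(e)
        e_kids = G.children[e]
        for d in tubes:
            d_kids = tree.children[d]
            best, tag = INF, None

            def consider(c, t):
                nonlocal best, tag, n_candidates
                n_candidates += 1
                if c < best:
                    best, tag = c, t

            if e_leaf and not d_kids:
                # base case: leaf edge in a leaf tube
                home = species_leaves.get(G.species_of(e))
                if d == home:
                    consider(0.0, ("base",))
                elif gain and d in outg:
                    consider(costs.gain, ("base-transfer", home, True))
                else:
                    consider(costs.transfer_norel, ("base-transfer", home,
                                                    False))
                cost_of[(e, d)] = best
                choice_of[(e, d)] = tag
                continue

            same_slice = [x for x in by_rank[S0.rank_of[d]] if x != d]
            # rule 4: divergence (preferred tie-break)
            if e_kids and len(d_kids) == 2:
                cdiv = 0.0 if (gain and d == d0) else costs.div
                for (x, y) in ((0, 1), (1, 0)):
                    consider(cost_of[(e_kids[x], d_kids[0])]
                             + cost_of[(e_kids[y], d_kids[1])] + cdiv,
                             ("4", x))
            # rule 2: survive in one child tube
            if len(d_kids) == 2:
                lcost0 = 0.0 if (gain and d == d0) else c_loss(d_kids[1])
                lcost1 = 0.0 if (gain and d == d0) else c_loss(d_kids[0])
                consider(cost_of[(e, d_kids[0])] + lcost0, ("2", 0))
                consider(cost_of[(e, d_kids[1])] + lcost1, ("2", 1))
            # rule 1: single child tube (subdivision / outgroup chain);
            # preferred over rule 3 on ties so that a cost-tied
            # duplication lands as low as the canonical mapping puts it
            if len(d_kids) == 1:
                consider(cost_of[(e, d_kids[0])], ("1",))
            # rule 3: duplication in d
            if e_kids:
                cdup = 0.0 if (gain and d in outg) else costs.dup
                consider(cost_of[(e_kids[0], d)] + cost_of[(e_kids[1], d)]
                         + cdup, ("3",))
            # rule 3': free split into the outgroup at the root tube
            if gain and e_kids and d == d0:
                top = min(outg, key=lambda v: S0.rank_of[v])
                for (x, y) in ((0, 1), (1, 0)):
                    consider(cost_of[(e_kids[x], d)]
                             + cost_of[(e_kids[y], top)], ("3p", x))
            # rule 5: duplication + transfer with retention into d' ~ d
            if e_kids:
                ctr = costs.gain if (gain and d in outg) else costs.transfer_ret
                for dp in same_slice:
                    if dp in outg:
                        continue
                    for (x, y) in ((0, 1), (1, 0)):
                        consider(cost_of[(e_kids[x], d)]
                                 + cost_of[(e_kids[y], dp)] + ctr,
                                 ("5", dp, x))
            # rule 6: transfer without retention into d' ~ d, then ...
            ctn = costs.gain if (gain and d in outg) else costs.transfer_norel
            for dp in same_slice:
                if dp in outg:
                    continue
                dp_kids = tree.children[dp]
                if len(dp_kids) == 1:
                    consider(cost_of[(e, dp_kids[0])] + ctn, ("6.1", dp))
                if len(dp_kids) == 2:
                    consider(cost_of[(e, dp_kids[0])] + ctn
                             + c_loss(dp_kids[1]), ("6.2", dp, 0))
                    consider(cost_of[(e, dp_kids[1])] + ctn
                             + c_loss(dp_kids[0]), ("6.2", dp, 1))
                if e_kids:
                    consider(cost_of[(e_kids[0], dp)]
                             + cost_of[(e_kids[1], dp)] + ctn + costs.dup,
                             ("6.3", dp))
                if e_kids and len(dp_kids) == 2:
                    for (x, y) in ((0, 1), (1, 0)):
                        consider(cost_of[(e_kids[x], dp_kids[0])]
                                 + cost_of[(e_kids[y], dp_kids[1])]
                                 + ctn + costs.div, ("6.4", dp, x))
                if e_kids:
                    for dpp in same_slice:
                        if dpp == dp or dpp in outg:
                            continue
                        for (x, y) in ((0, 1), (1, 0)):
                            consider(cost_of[(e_kids[x], dp)]
                                     + cost_of[(e_kids[y], dpp)]
                                     + ctn + costs.transfer_ret,
                                     ("6.5", dp, dpp, x))
            cost_of[(e, d)] = best
            choice_of[(e, d)] = tag

    return InnerTreeTable(cost_of, choice_of, G, S0, costs, gain,
                          n_candidates)


# ---------------------------------------------------------------------------
# backtracking
# ---------------------------------------------------------------------------

def best_scenario(table: InnerTreeTable, G: RootedTree = None,
                  S0: SlicedSpeciesTree = None,
                  costs: EventCosts = None) -> Scenario:
    """Backtrack the minimizing choices from the root pair into a scenario:
    the gene tree with transfer insertions, its mapping, and the events."""
    G = G or table.gene_tree
    S0 = S0 or table.sliced
    costs = costs or table.costs
    tree = S0.tree
    gain = table.gain
    outg = S0.outgroup_tubes
    if not math.isfinite(table.root_entry):
        raise TreeError("no feasible scenario under these costs")
    species_leaves = {tree.species_of(l): l for l in tree.labels}

    inserted = {g: [] for g in G.children if g != G.superroot}
    fmap = {G.superroot: ("t", tree.root)}
    inv = EventInventory()

    def transfer_event(e, donor, recipient, retention):
        if gain and donor in outg:
            inv.gains.append((e, recipient))
        else:
            inv.transfers.append((e, donor, recipient, retention))

    def walk(e, d):
        tag = table.choice_of[(e, d)]
        kind = tag[0]
        e_kids = G.children[e]
        d_kids = tree.children[d]
        if kind == "base":
            fmap[e] = ("v", d)
        elif kind == "base-transfer":
            home = tag[1]
            transfer_event(e, d, home, False)
            inserted[e] += [("t", d), ("t", home)]
            fmap[e] = ("v", home)
        elif kind == "1":
            walk(e, d_kids[0])
        elif kind == "2":
            i = tag[1]
            other = d_kids[1 - i]
            if not (gain and d == tree.root):
                inv.losses.append((e, d, _loss_flag(S0, other,
                                                    G.species_set())))
            walk(e, d_kids[i])
        elif kind == "3":
            if not (gain and d in outg):
                inv.duplications.append((e, d))
            fmap[e] = ("t", d)
            walk(e_kids[0], d)
            walk(e_kids[1], d)
        elif kind == "3p":
            x = tag[1]
            top = min(outg, key=lambda v: S0.rank_of[v])
            fmap[e] = ("t", d)
            walk(e_kids[x], d)
            walk(e_kids[1 - x], top)
        elif kind == "4":
            x = tag[1]
            if not (gain and d == tree.root):
                inv.divergences.append((e, d))
            fmap[e] = ("v", d)
            walk(e_kids[x], d_kids[0])
            walk(e_kids[1 - x], d_kids[1])
        elif kind == "5":
            dp, x = tag[1], tag[2]
            recip = e_kids[1 - x]
            transfer_event(recip, d, dp, True)
            inserted[recip].append(("t", dp))
            fmap[e] = ("t", d)
            walk(e_kids[x], d)
            walk(recip, dp)
        elif kind.startswith("6"):
            dp = tag[1]
            transfer_event(e, d, dp, False)
            inserted[e] += [("t", d), ("t", dp)]
            dp_kids = tree.children[dp]
            if kind == "6.1":
                walk(e, dp_kids[0])
            elif kind == "6.2":
                i = tag[2]
                inv.losses.append((e, dp, _loss_flag(S0, dp_kids[1 - i],
                                                     G.species_set())))
                walk(e, dp_kids[i])
            elif kind == "6.3":
                inv.duplications.append((e, dp))
                fmap[e] = ("t", dp)
                walk(e_kids[0], dp)
                walk(e_kids[1], dp)
            elif kind == "6.4":
                x = tag[2]
                inv.divergences.append((e, dp))
                fmap[e] = ("v", dp)
                walk(e_kids[x], dp_kids[0])
                walk(e_kids[1 - x], dp_kids[1])
            elif kind == "6.5":
                dpp, x = tag[2], tag[3]
                recip = e_kids[1 - x]
                inv.transfers.append((recip, dp, dpp, True))
                inserted[recip].append(("t", dpp))
                fmap[e] = ("t", dp)
                walk(e_kids[x], dp)
                walk(recip, dpp)
        else:  # pragma: no cover
            raise AssertionError(f"unknown rule tag {tag!r}")

    walk(G.root, tree.root)
    inv.total_cost = table.root_entry

    # materialize G' with the transfer insertions
    parent = dict(G.parent)
    children = {v: list(cs) for v, cs in G.children.items()}
    labels = dict(G.labels)
    scen_vertices = set()
    next_id = max(children) + 1
    for e, targets in inserted.items():
        upper = parent[e]
        for t in targets:  # top-down
            w = next_id
            next_id += 1
            scen_vertices.add(w)
            children[upper] = [w if c == e else c for c in children[upper]]
            parent[w] = upper
            children[w] = [e]
            parent[e] = w
            fmap[w] = t
            upper = w
    gprime = RootedTree(parent, children, G.superroot, labels,
                        subdivision=frozenset(scen_vertices))
    # leaves of G map to their species leaves
    for l in G.labels:
        fmap.setdefault(l, ("v", species_leaves[G.species_of(l)]))
    return Scenario(gprime, Mapping(fmap), inv, table.root_entry)


def scenario_report(sc: Scenario):
    """Per-tube event counts plus transfer arcs, for human consumption."""
    if not sc.gene_tree_prime.labels:
        raise TreeError("empty gene tree")
    per_tube = {}

    def bump(loc, kind):
        per_tube.setdefault(loc, {"duplications": 0, "divergences": 0,
                                  "losses": 0})[kind] += 1

    for _, d in sc.events.duplications:
        bump(d, "duplications")
    for _, s in sc.events.divergences:
        bump(s, "divergences")
    for _, s, _ in sc.events.losses:
        bump(s, "losses")
    arcs = [(donor, recip, ret)
            for _, donor, recip, ret in sc.events.transfers]
    return {"per_tube": per_tube, "transfer_arcs": arcs,
            "gains": list(sc.events.gains),
            "total_cost": sc.total_cost}


# ---------------------------------------------------------------------------
# brute-force oracle (test scale): enumerate inner trees without memoization
# ---------------------------------------------------------------------------

def enumerate_inner_cost(G: RootedTree, S0: SlicedSpeciesTree,
                         costs: EventCosts, guard: int = 8) -> float:
    """Minimum cost over every inner tree licensed by the rules, computed
    by direct recursion over rule applications (no table).  Independent
    check of the DP at tiny sizes."""
    if len(G.labels) + len(S0.tree.labels) > guard:
        raise TreeError("oracle restricted to tiny instances")
    tree = S0.tree
    species_leaves = {tree.species_of(l): l for l in tree.labels}
    gene_species = G.species_set()
    by_rank = {}
    for d in S0.tubes():
        by_rank.setdefault(S0.rank_of[d], []).append(d)

    def c_loss(sub):
        return (costs.loss_explicit if tree.clade(sub) & gene_species
                else costs.loss_implicit)

    def rec(e, d):
        e_kids = G.children[e]
        d_kids = tree.children[d]
        if not e_kids and not d_kids:
            return 0.0 if d == species_leaves[G.species_of(e)] \
                else costs.transfer_norel
        alts = []
        same_slice = [x for x in by_rank[S0.rank_of[d]] if x != d]
        if len(d_kids) == 1:
            alts.append(rec(e, d_kids[0]))
        if len(d_kids) == 2:
            for i in (0, 1):
                alts.append(rec(e, d_kids[i]) + c_loss(d_kids[1 - i]))
        if e_kids:
            alts.append(rec(e_kids[0], d) + rec(e_kids[1], d) + costs.dup)
        if e_kids and len(d_kids) == 2:
            for x in (0, 1):
                alts.append(rec(e_kids[x], d_kids[0])
                            + rec(e_kids[1 - x], d_kids[1]) + costs.div)
        if e_kids:
            for dp in same_slice:
                for x in (0, 1):
                    alts.append(rec(e_kids[x], d) + rec(e_kids[1 - x], dp)
                                + costs.transfer_ret)
        for dp in same_slice:
            dpk = tree.children[dp]
            if len(dpk) == 1:
                alts.append(rec(e, dpk[0]) + costs.transfer_norel)
            if len(dpk) == 2:
                for i in (0, 1):
                    alts.append(rec(e, dpk[i]) + costs.transfer_norel
                                + c_loss(dpk[1 - i]))
            if e_kids:
                alts.append(rec(e_kids[0], dp) + rec(e_kids[1], dp)
                            + costs.transfer_norel + costs.dup)
                if len(dpk) == 2:
                    for x in (0, 1):
                        alts.append(rec(e_kids[x], dpk[0])
                                    + rec(e_kids[1 - x], dpk[1])
                                    + costs.transfer_norel + costs.div)
                for dpp in same_slice:
                    if dpp == dp:
                        continue
                    for x in (0, 1):
                        alts.append(rec(e_kids[x], dp)
                                    + rec(e_kids[1 - x], dpp)
                                    + costs.transfer_norel
                                    + costs.transfer_ret)
        return min(alts) if alts else INF

    return rec(G.root, tree.root)
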