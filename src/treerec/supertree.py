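"""Conditional supertree construction from gene trees (duplications and
losses only).

Phase 1 is an exact dynamic program over *basic sets*: members of the
clade family P that can be partitioned within P down to singletons.  For
every basic set V it builds the basic tree S(V) and its cost c(V) by
minimizing, over partitions <V1, V2>, the recursion

    c(V, V1, V2) = c(V1) + c(V2) + c_div*q1 + c_dup*q2
                   + c_los1*q3' + c_los2*q3''

where the q-counts enumerate, directly on the gene trees, the divergences
at the join root, the duplications in its root tube, and the explicit and
implicit losses at the join root that the merged tree would incur.  If the
full species set V0 is basic, S(V0) is the conditional global optimum.

Phase 2 is a reliability-weighted augmentation heuristic that assembles a
supertree one species at a time, scoring each candidate by c * (2 - R)
with reliability R = (c' - c) / c' (c and c' the best and second-best
costs).  When every basic tree is a pruning of one reference tree and
implicit losses (and divergences) cost nothing, the result has cost zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .reconcile import EventCosts, compute_alpha, infer_events, par_count
from .trees import CladeFamily, RootedTree, TreeError, prune_to, write_newick

__all__ = ["BasicTreeTable", "AugmentationTrace", "q_counts", "phase1",
           "phase2", "tree_cost_against_basics", "modified_phase1",
           "merge_trees"]


@dataclass
class BasicTreeTable:
    """Phase-1 product: basic set -> (basic tree, cost, winning partition)."""

    entries: dict = field(default_factory=dict)  # V -> (tree, cost, (V1,V2))
    family: CladeFamily = None
    n_partition_evals: int = 0  # work proxy for complexity trend checks

    def is_basic(self, V):
        return frozenset(V) in self.entries

    def tree(self, V):
        return self.entries[frozenset(V)][0]

    def cost(self, V):
        return self.entries[frozenset(V)][1]

    def basic_trees(self, min_leaves=2):
        return [t for V, (t, _, _) in sorted(
                    self.entries.items(), key=lambda kv: sorted(kv[0]))
                if len(V) >= min_leaves]


@dataclass
class AugmentationTrace:
    """Phase-2 log: one step per accepted base triple / added species."""

    steps: list = field(default_factory=list)
    unreliable: set = field(default_factory=set)
    terminated_early: bool = False


def merge_trees(t1: RootedTree, t2: RootedTree) -> RootedTree:
    """Join two trees under a common new root."""

    def nested(t, v):
        if t.is_leaf(v):
            return t.labels[v]
        return [nested(t, c) for c in t.children[v]]

    return RootedTree.from_nested([nested(t1, t1.root), nested(t2, t2.root)])


# ---------------------------------------------------------------------------
# q-counts for the join-cost recursion
# ---------------------------------------------------------------------------

def q_counts(Gjs, V1, V2):
    """Event counts at the join of V1 and V2, read off the gene trees.

    Returns (q1, q2, q3p, q3pp): divergences at the join root, duplications
    in its root tube, explicit losses, implicit losses.  A gene edge loses
    at the join root when its lower clade sits inside one half while its
    upper end maps strictly above (sibling clade in neither half, or the
    superroot); the loss is explicit for trees touching both halves and
    implicit for trees touching exactly one.
    """
    V1, V2 = frozenset(V1), frozenset(V2)
    if not V1 or not V2 or V1 & V2:
        raise TreeError("V1 and V2 must be nonempty and disjoint")
    V = V1 | V2
    q1 = q2 = q3p = q3pp = 0
    for G in Gjs:
        root_clade = G.clade(G.root)
        touches1, touches2 = bool(root_clade & V1), bool(root_clade & V2)
        cond_i = touches1 and touches2
        cond_ii = touches1 != touches2
        for g in G.children:
            if g == G.superroot or G.is_leaf(g):
                continue
            kids = [G.clade(c) for c in G.children[g]]
            in1 = [k <= V1 for k in kids]
            in2 = [k <= V2 for k in kids]
            if len(kids) == 2 and ((in1[0] and in2[1]) or
                                   (in2[0] and in1[1])):
                q1 += 1
            if G.clade(g) <= V and any((k & V1) and (k & V2) for k in kids):
                q2 += 1
        if not (cond_i or cond_ii):
            continue
        for e in G.children:  # edges named by lower vertex, incl. root edge
            if e == G.superroot:
                continue
            ce = G.clade(e)
            if not (ce <= V1 or ce <= V2):
                continue
            up = G.parent[e]
            if up == G.superroot:
                hit = True
            else:
                siblings = [c for c in G.children[up] if c != e]
                hit = all(not (G.clade(c) <= V1 or G.clade(c) <= V2)
                          for c in siblings)
            if hit:
                if cond_i:
                    q3p += 1
                else:
                    q3pp += 1
    return q1, q2, q3p, q3pp


def _partition_cost(Gjs, costs, c1, c2, V1, V2):
    q1, q2, q3p, q3pp = q_counts(Gjs, V1, V2)
    total = c1 + c2
    for n, w in ((q1, costs.div), (q2, costs.dup),
                 (q3p, costs.loss_explicit), (q3pp, costs.loss_implicit)):
        if n:
            total += w * n
    return total


# ---------------------------------------------------------------------------
# Phase 1
# ---------------------------------------------------------------------------

def phase1(Gjs, P: CladeFamily, costs: EventCosts = None) -> BasicTreeTable:
    """Build the basic-tree table over the clade family P.

    Singletons are always basic (cost c_dup * sum_j Par(Gj, s)); a larger
    member of P is basic when some partition into two basic members exists,
    and gets the minimal-cost such partition.  Ties go to the
    lexicographically smallest sorted pair.
    """
    costs = costs or EventCosts()
    table = BasicTreeTable(family=P)
    universe = P.universe
    for s in sorted(universe):
        V = frozenset([s])
        c = costs.dup * sum(par_count(G, s) for G in Gjs)
        table.entries[V] = (RootedTree.from_nested(s), c, None)

    members = sorted({m for m in P.members if len(m) >= 2},
                     key=lambda m: (len(m), sorted(m)))
    halves = sorted(P.members | {frozenset([s]) for s in universe},
                    key=lambda m: (len(m), sorted(m)))
    for V in members:
        best = None
        for V1 in halves:
            if len(V1) > len(V) - 1 or not V1 < V:
                continue
            V2 = V - V1
            if V2 not in table.entries or V1 not in table.entries:
                continue
            if V2 not in P.members and len(V2) > 1:
                continue
            key = tuple(sorted(V1)), tuple(sorted(V2))
            if key[0] > key[1]:
                continue  # each unordered pair once, smaller half first
            table.n_partition_evals += 1
            c = _partition_cost(Gjs, costs, table.cost(V1), table.cost(V2),
                                V1, V2)
            if best is None or c < best[0] or (c == best[0] and
                                               key < best[1]):
                best = (c, key, V1, V2)
        if best is not None:
            c, _, V1, V2 = best
            tree = merge_trees(table.tree(V1), table.tree(V2))
            table.entries[V] = (tree, c, (V1, V2))
    return table


# ---------------------------------------------------------------------------
# Phase 2
# ---------------------------------------------------------------------------

def tree_cost_against_basics(S: RootedTree, table, Gjs=None,
                             costs: EventCosts = None) -> float:
    """Total canonical-mapping cost of every basic tree (>= 2 leaves),
    pruned to S's label set, embedded into S.  ``table`` may be a
    BasicTreeTable or a plain list of trees (the modified-Phase-1 output).
    """
    costs = costs or EventCosts()
    basics = (table.basic_trees() if isinstance(table, BasicTreeTable)
              else list(table))
    keep = S.species_set()
    total = 0.0
    for B in basics:
        overlap = B.species_set() & keep
        if len(overlap) < 2:
            continue
        Bp = prune_to(B, keep)
        if len(Bp.labels) < 2:
            continue
        inv = infer_events(Bp, S, compute_alpha(Bp, S), costs)
        total += inv.total_cost
    return total


def _all_topologies(labels):
    """Every rooted binary topology over the labels (tiny n only)."""
    labels = sorted(labels)
    trees = [labels[0]]
    for lab in labels[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, lab))
        trees = nxt
    return [RootedTree.from_nested(t) for t in trees]


def _insert_everywhere(nested, lab):
    out = [[nested, lab]]
    if isinstance(nested, list):
        left, right = nested
        out += [[l, right] for l in _insert_everywhere(left, lab)]
        out += [[left, r] for r in _insert_everywhere(right, lab)]
    return out


def _best_two(scored):
    """(c, c', argmin tree) from (cost, key, tree) candidates; c' is the
    smallest cost strictly greater than c, or None."""
    scored = sorted(scored, key=lambda x: (x[0], x[1]))
    c, _, tree = scored[0]
    cp = next((x[0] for x in scored if x[0] > c), None)
    return c, cp, tree


def phase2(table, Gjs, V0=None, costs: EventCosts = None):
    """Reliability-weighted augmentation of the basic trees into one
    supertree over V0.  Returns (tree, trace); ``trace.terminated_early``
    flags the no-reliable-triple outcome.
    """
    costs = costs or EventCosts()
    if V0 is None:
        V0 = frozenset().union(*(G.species_set() for G in Gjs))
    V0 = frozenset(V0)
    trace = AugmentationTrace()
    if len(V0) < 3:
        raise TreeError("phase 2 needs at least three species")

    # base: best 3-species tree by c * (2 - R)
    candidates = []
    for trip in itertools.combinations(sorted(V0), 3):
        scored = [(tree_cost_against_basics(t, table, Gjs, costs),
                   write_newick(t), t) for t in _all_topologies(trip)]
        c, cp, tree = _best_two(scored)
        if cp is None:
            continue
        R = (cp - c) / cp
        if R > 0:
            candidates.append((c * (2 - R), trip, c, cp, R, tree))
    if not candidates:
        trace.terminated_early = True
        return None, trace
    candidates.sort(key=lambda x: (x[0], x[1]))
    score, trip, c, cp, R, current = candidates[0]
    trace.steps.append({"added": trip, "c": c, "c_prime": cp,
                        "reliability": R, "tree": write_newick(current)})

    remaining = sorted(V0 - frozenset(trip))
    while remaining:
        per_species = []
        for s in remaining:
            scored = [(tree_cost_against_basics(t, table, Gjs, costs),
                       write_newick(t), t)
                      for t in _insertions(current, s)]
            c, cp, tree = _best_two(scored)
            if cp is None:
                per_species.append((s, None))
                continue
            R = (cp - c) / cp
            per_species.append((s, (c * (2 - R), c, cp, R, tree)))
        usable = [(info[0], s, info) for s, info in per_species
                  if info is not None]
        for s, info in per_species:
            if info is None:
                trace.unreliable.add(s)
                remaining.remove(s)
        if not usable:
            break
        usable.sort(key=lambda x: (x[0], x[1]))
        _, s, (score, c, cp, R, tree) = usable[0]
        current = tree
        remaining.remove(s)
        trace.steps.append({"added": s, "c": c, "c_prime": cp,
                            "reliability": R, "tree": write_newick(current)})
    return current, trace


def _insertions(tree: RootedTree, species: str):
    """All trees obtained by attaching a new leaf on each edge of ``tree``,
    including its root edge."""

    def nested(v):
        if tree.is_leaf(v):
            return tree.labels[v]
        return [nested(c) for c in tree.children[v]]

    base = nested(tree.root)
    out = [RootedTree.from_nested([base, species])]  # root edge

    def rec(node):
        # yields nested structures with the leaf inserted somewhere in node
        yield [node, species]
        if isinstance(node, list):
            left, right = node
            for l in rec(left):
                yield [l, right]
            for r in rec(right):
                yield [left, r]

    for cand in rec(base):
        if cand == [base, species]:
            continue  # already added as the root-edge insertion
        out.append(RootedTree.from_nested(cand))
    return out


# ---------------------------------------------------------------------------
# Modified Phase 1 (pruned instances)
# ---------------------------------------------------------------------------

def modified_phase1(Gjs, P: CladeFamily, costs: EventCosts = None):
    """Per-member pruned Phase 1: for each V in P, prune every gene tree
    and every family member to V and run Phase 1 on the pruned instance;
    record its basic tree over V when one exists.  Returns V -> (tree,
    cost).  Any V basic for the full instance is basic for its pruned one.
    """
    costs = costs or EventCosts()
    out = {}
    for V in sorted(P.members, key=lambda m: (len(m), sorted(m))):
        pruned_G = []
        for G in Gjs:
            if G.species_set() & V:
                pruned_G.append(prune_to(G, V))
        PV = CladeFamily(V)
        for A in P.members:
            if A & V:
                PV.members.add(A & V)
        PV = PV.with_singletons()
        sub = phase1(pruned_G, PV, costs)
        if sub.is_basic(V):
            out[V] = (sub.tree(V), sub.cost(V))
    return out
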