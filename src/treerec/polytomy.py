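"""Binarization of polytomous gene trees against a binary species tree.

A *candidate binarization* resolves each polytomous vertex by repeatedly
splitting its children into two parts under new intercalating vertices.
The *paralogous binarization* G## is the candidate binarization that, for
every species tube d, minimizes the number of gene edges *entering* d;
all paralogous binarizations of a fixed pair (G, S) have equal canonical
embedding cost, so any one of them may be used downstream.

An edge e enters tube d when d(e_upper) is strictly above d and d is
weakly above d(e_lower), where d(g) is the tube of the canonical image of
g (the image itself when it is a tube, else the tube just above it).  The
entering edges of d partition into *bundles* by their upper terminus;
p(G, d) bundles means p(G, d) entering edges in G##.

The bundle machinery also yields the polytomous Phase-1 recursion: the
join-root event counts of the supertree DP are expressed through bundle
counts n, n1, n2 and shared-parent bundle pairs k, so the supertree can be
built from polytomous gene trees without materializing binarizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .reconcile import EventCosts, compute_alpha
from .supertree import BasicTreeTable, merge_trees
from .trees import CladeFamily, RootedTree, TreeError

__all__ = ["Bundle", "PolytomousCounts", "enters_tube", "bundles_for",
           "binarization_step", "paralogous_binarization", "par_prime",
           "poly_q_counts", "phase1_polytomous",
           "enumerate_candidate_binarizations", "is_paralogous_binarization"]


@dataclass(frozen=True)
class Bundle:
    """Maximal set of same-parent gene edges entering one tube."""

    tube: int
    parent_vertex: int          # F+, the shared upper terminus
    edges: frozenset            # gene edges, named by lower vertex


@dataclass
class PolytomousCounts:
    """Bundle counts feeding the polytomous join-cost recursion."""

    n: int = 0      # bundles for the tube above the join root
    n1: int = 0     # bundles for the tube into the V1 half
    n2: int = 0
    k: int = 0      # bundle pairs for (d1, d2) sharing a parent vertex
    n1p: int = 0    # the same, restricted to trees touching both halves
    n2p: int = 0
    kp: int = 0
    n1pp: int = 0   # restricted to trees touching exactly one half
    n2pp: int = 0
    kpp: int = 0


def _tube_of(G: RootedTree, S: RootedTree, alpha, g):
    """d(g): the canonical image as a tube (the image when it is a tube,
    else the tube entering the image vertex)."""
    kind, x = alpha[g]
    return x  # tube id == lower vertex id for both cases


def enters_tube(G: RootedTree, S: RootedTree, e, d, alpha=None) -> bool:
    """True iff gene edge e (named by its lower vertex) enters tube d."""
    alpha = alpha or compute_alpha(G, S)
    up = G.parent[e]
    d_lower = _tube_of(G, S, alpha, e)
    d_upper = _tube_of(G, S, alpha, up)
    # d(e+) strictly above d, and d weakly above d(e_lower)
    return (d_upper != d and S.is_weak_ancestor(d_upper, d)
            and S.is_weak_ancestor(d, d_lower))


def bundles_for(G: RootedTree, S: RootedTree, d, alpha=None):
    """The bundles of G for tube d, sorted by parent vertex."""
    alpha = alpha or compute_alpha(G, S)
    by_parent = {}
    for e in G.children:
        if e == G.superroot:
            continue
        if enters_tube(G, S, e, d, alpha):
            by_parent.setdefault(G.parent[e], set()).add(e)
    return [Bundle(d, p, frozenset(es))
            for p, es in sorted(by_parent.items())]


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarization_step(Gp: RootedTree, g, A, B) -> RootedTree:
    """One resolution step: split the children of the polytomous vertex g
    into parts A and B under (at most) two new part-ancestor vertices;
    a singleton part keeps its vertex directly under g."""
    A, B = set(A), set(B)
    kids = set(Gp.children[g])
    if not A or not B or A & B or A | B != kids:
        raise TreeError("parts must be nonempty, disjoint, and cover the "
                        "children")
    if len(kids) < 3:
        raise TreeError("vertex is not polytomous")
    parent = dict(Gp.parent)
    children = {v: list(cs) for v, cs in Gp.children.items()}
    next_id = max(children) + 1
    new_kids = []
    for part in (A, B):
        ordered = [c for c in Gp.children[g] if c in part]
        if len(ordered) == 1:
            new_kids.append(ordered[0])
            continue
        w = next_id
        next_id += 1
        children[w] = ordered
        parent[w] = g
        for c in ordered:
            parent[c] = w
        new_kids.append(w)
    children[g] = new_kids
    return RootedTree(parent, children, Gp.superroot, Gp.labels,
                      subdivision=Gp.subdivision, outgroup=Gp.outgroup)


def paralogous_binarization(G: RootedTree, S: RootedTree) -> RootedTree:
    """Resolve every polytomy of G so that each tube of S receives the
    minimal number of entering edges (one per bundle of G).

    At a polytomous vertex g with tube d(g) over child tubes d1, d2, the
    children split into those staying in d(g), those below d1 and those
    below d2; the first part (if any) separates from the union of the
    others, and a lone first part splits first-child-versus-rest (any
    split is cost-equivalent).
    """
    if not S.is_binary:
        raise TreeError("species tree must be binary")
    Gp = G.copy()
    while True:
        poly = [v for v in Gp.postorder()
                if v != Gp.superroot and len(Gp.children[v]) > 2]
        if not poly:
            return Gp
        g = poly[0]
        alpha = compute_alpha(Gp, S)
        dg = _tube_of(Gp, S, alpha, g)
        d_kids = S.children[dg]
        part1 = [c for c in Gp.children[g]
                 if _tube_of(Gp, S, alpha, c) == dg]
        rest = {c: _tube_of(Gp, S, alpha, c)
                for c in Gp.children[g] if c not in part1}
        if len(d_kids) == 2:
            part2 = [c for c, t in rest.items()
                     if S.is_weak_ancestor(d_kids[0], t)]
            part3 = [c for c, t in rest.items()
                     if S.is_weak_ancestor(d_kids[1], t)]
        else:  # d(g) is a leaf tube: every child is a same-species paralog
            part2, part3 = [], []
        if part1 and (part2 or part3):
            A, B = part1, part2 + part3
        elif part1:
            A, B = part1[:1], part1[1:]
        else:
            A, B = part2, part3
        Gp = binarization_step(Gp, g, A, B)


def enumerate_candidate_binarizations(G: RootedTree, S: RootedTree = None,
                                      guard: int = 6):
    """Every candidate binarization (exhaustive; tiny trees only).  Oracle
    for the entering-edge minimality and cost-invariance properties."""
    if len(G.labels) > guard:
        raise TreeError("binarization enumeration is for test scale only")

    def resolutions(kid_structs):
        # all binary joins of the given child structures
        if len(kid_structs) == 1:
            yield kid_structs[0]
            return
        if len(kid_structs) == 2:
            yield [kid_structs[0], kid_structs[1]]
            return
        first = kid_structs[0]
        others = kid_structs[1:]
        seen = set()
        for r in range(0, len(others) + 1):
            for comb in combinations(range(len(others)), r):
                A = [first] + [others[i] for i in comb]
                B = [others[i] for i in range(len(others))
                     if i not in comb]
                if not B:
                    continue
                for ra in resolutions(A):
                    for rb in resolutions(B):
                        key = repr([ra, rb])
                        if key not in seen:
                            seen.add(key)
                            yield [ra, rb]

    def nested(v):
        if G.is_leaf(v):
            return [G.labels[v]]
        opts = []
        kid_opts = [nested(c) for c in G.children[v]]
        for combo in _product(kid_opts):
            opts.extend(resolutions(list(combo)))
        return opts

    def _product(lists):
        if not lists:
            yield ()
            return
        for head in lists[0]:
            for tail in _product(lists[1:]):
                yield (head,) + tail

    seen = set()
    for struct in nested(G.root):
        t = RootedTree.from_nested(struct)
        key = _canon(t)
        if key not in seen:
            seen.add(key)
            yield t


def _canon(t: RootedTree):
    def rec(v):
        if t.is_leaf(v):
            return t.labels[v]
        return tuple(sorted((rec(c) for c in t.children[v]), key=str))
    return rec(t.root)


def _leaf_tube_bundles(G: RootedTree, s: str):
    """Bundles for the leaf tube of species s, read off clades alone: an
    edge enters iff its lower clade is {s} while its upper terminus is the
    superroot or has a different clade."""
    singleton = frozenset([s])
    by_parent = {}
    for e in G.children:
        if e == G.superroot or G.clade(e) != singleton:
            continue
        up = G.parent[e]
        if up == G.superroot or G.clade(up) != singleton:
            by_parent.setdefault(up, set()).add(e)
    return by_parent


def par_prime(G: RootedTree, S: RootedTree, s: str) -> int:
    """Par'(G, s): duplications any paralogous binarization places in the
    leaf tube of s; equals (leaves below the tube's bundle edges) minus
    (number of bundles)."""
    if S is not None and s not in {S.species_of(l) for l in S.labels}:
        raise TreeError(f"unknown species {s!r}")
    bundles = _leaf_tube_bundles(G, s)
    L = sum(sum(1 for u in G.preorder(e) if G.is_leaf(u))
            for es in bundles.values() for e in es)
    return L - len(bundles)


def is_paralogous_binarization(cand: RootedTree, G: RootedTree,
                               S: RootedTree) -> bool:
    """True iff the candidate binarization realizes, for every tube, the
    minimal entering-edge count p(G, d) *and* the shared-parent bundle
    pairing (entering edges of sibling tubes share an upper terminus
    exactly when the corresponding bundles of G share their parent
    vertex).  The construction procedure guarantees both; together they
    pin the embedding cost."""
    alpha_G = compute_alpha(G, S)
    alpha_c = compute_alpha(cand, S)
    for d in S.children:
        if d == S.superroot:
            continue
        want = len(bundles_for(G, S, d, alpha_G))
        have = sum(1 for e in cand.children if e != cand.superroot
                   and enters_tube(cand, S, e, d, alpha_c))
        if want != have:
            return False
    # shared-parent pairing across sibling tubes
    for v in S.children:
        if v == S.superroot or S.is_leaf(v):
            continue
        d1, d2 = S.children[v]
        k = len(set(_bundle_parents(G, S, d1, alpha_G))
                & set(_bundle_parents(G, S, d2, alpha_G)))
        ent1 = {cand.parent[e] for e in cand.children
                if e != cand.superroot
                and enters_tube(cand, S, e, d1, alpha_c)}
        ent2 = {cand.parent[e] for e in cand.children
                if e != cand.superroot
                and enters_tube(cand, S, e, d2, alpha_c)}
        if len(ent1 & ent2) != k:
            return False
    return True


def _bundle_parents(G, S, d, alpha):
    return [b.parent_vertex for b in bundles_for(G, S, d, alpha)]


# ---------------------------------------------------------------------------
# polytomous Phase 1
# ---------------------------------------------------------------------------

def _conceptual_bundles(G: RootedTree, half: frozenset, V: frozenset):
    """Bundles for the tube into the `half` side of a hypothetical join of
    the two halves of V, read directly off clades: an edge enters when its
    lower clade sits inside the half while its upper end is the superroot
    or has a clade not inside the half."""
    by_parent = {}
    for e in G.children:
        if e == G.superroot:
            continue
        if not G.clade(e) <= half:
            continue
        up = G.parent[e]
        if up == G.superroot or not (G.clade(up) <= half):
            by_parent.setdefault(up, set()).add(e)
    return by_parent


def poly_q_counts(Gjs, V1, V2) -> PolytomousCounts:
    """Bundle counts for the conceptual tubes d (above the join root of
    V = V1 | V2) and d1, d2 (into the halves), computed on the polytomous
    gene trees without materializing a binarization."""
    V1, V2 = frozenset(V1), frozenset(V2)
    if not V1 or not V2 or V1 & V2:
        raise TreeError("V1 and V2 must be nonempty and disjoint")
    V = V1 | V2
    out = PolytomousCounts()
    for G in Gjs:
        root_clade = G.clade(G.root)
        t1, t2 = bool(root_clade & V1), bool(root_clade & V2)
        cond_i = t1 and t2
        cond_ii = t1 != t2
        b1 = _conceptual_bundles(G, V1, V)
        b2 = _conceptual_bundles(G, V2, V)
        bV = _conceptual_bundles(G, V, V)
        n1, n2, n = len(b1), len(b2), len(bV)
        k = len(set(b1) & set(b2))
        out.n += n
        out.n1 += n1
        out.n2 += n2
        out.k += k
        if cond_i:
            out.n1p += n1
            out.n2p += n2
            out.kp += k
        elif cond_ii:
            out.n1pp += n1
            out.n2pp += n2
            out.kpp += k
    return out


def _poly_partition_cost(Gjs, costs: EventCosts, c1, c2, V1, V2):
    q = poly_q_counts(Gjs, V1, V2)
    total = c1 + c2
    for cnt, w in ((q.k, costs.div),
                   (q.n1 + q.n2 - q.n - q.k, costs.dup),
                   (q.n1p + q.n2p - 2 * q.kp, costs.loss_explicit),
                   (q.n1pp + q.n2pp - 2 * q.kpp, costs.loss_implicit)):
        if cnt:
            total += w * cnt
    return total


def phase1_polytomous(Gjs, P: CladeFamily,
                      costs: EventCosts = None) -> BasicTreeTable:
    """Phase 1 for polytomous gene trees: identical control flow to the
    binary recursion, with the join-root event term expressed through
    bundle counts and the singleton base using Par'."""
    costs = costs or EventCosts()
    table = BasicTreeTable(family=P)
    universe = P.universe
    # singleton base: duplications of a paralogous binarization in the
    # leaf tube (Par'), computed from clades alone
    for s in sorted(universe):
        V = frozenset([s])
        tot = sum(par_prime(G, None, s) for G in Gjs
                  if s in G.species_set())
        table.entries[V] = (RootedTree.from_nested(s), costs.dup * tot, None)

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
                continue
            c = _poly_partition_cost(Gjs, costs, table.cost(V1),
                                     table.cost(V2), V1, V2)
            if best is None or c < best[0] or (c == best[0] and
                                               key < best[1]):
                best = (c, key, V1, V2)
        if best is not None:
            c, _, V1, V2 = best
            table.entries[V] = (merge_trees(table.tree(V1), table.tree(V2)),
                                c, (V1, V2))
    return table
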