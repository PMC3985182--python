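"""Rooted-tree data model for reconciliation.

Trees are rooted and oriented downwards.  Every tree carries an auxiliary
*superroot* above its root, and the edge superroot->root is the *root edge*
(root tube for a species tree).  Edges of a species tree are called *tubes*;
a tube is identified by its lower vertex, so the root tube is identified by
the root and every non-superroot vertex names exactly one tube.

Gene leaves are labelled ``geneID@species`` (species = substring after the
last ``@``); a bare label is its own species.  Species-tree leaf labels must
be pairwise distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "RootedTree",
    "SlicedSpeciesTree",
    "CladeFamily",
    "TreeError",
    "parse_newick",
    "write_newick",
    "clade_of",
    "lca_of",
    "prune_to",
    "assign_time_slices",
]

OUTGROUP_LABEL = "*outgroup*"


class TreeError(ValueError):
    """Malformed tree, label, or Newick input."""


class RootedTree:
    """Rooted tree with a superroot and integer vertex identifiers.

    Vertices are integers ``0 .. n-1``.  ``children[v]`` preserves input
    order; ``parent[v]`` is ``None`` only for the superroot.  Single-child
    vertices are allowed only for the superroot and for vertices explicitly
    flagged as subdivision (time-slice) or scenario insertions.
    """

    def __init__(self, parent, children, superroot, labels,
                 subdivision=frozenset(), outgroup=frozenset(),
                 validate=True):
        self.parent = dict(parent)
        self.children = {v: list(cs) for v, cs in children.items()}
        self.superroot = superroot
        self.labels = dict(labels)  # leaf vertex -> full label
        self.subdivision = frozenset(subdivision)
        self.outgroup = frozenset(outgroup)
        self._clades = None
        self._depth = None
        if validate:
            self._check()

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_nested(cls, nested, subdivision=(), outgroup=()):
        """Build from a nested structure: a leaf label (str) or a list of
        nested structures.  A superroot is added above the outermost node."""
        parent, children, labels = {}, {}, {}
        counter = [0]

        def build(node):
            v = counter[0]
            counter[0] += 1
            children[v] = []
            if isinstance(node, str):
                labels[v] = node
            else:
                for child in node:
                    c = build(child)
                    parent[c] = v
                    children[v].append(c)
            return v

        root = build(nested)
        sr = counter[0]
        children[sr] = [root]
        parent[root] = sr
        parent[sr] = None
        return cls(parent, children, sr, labels,
                   subdivision=subdivision, outgroup=outgroup)

    def _check(self):
        if self.parent.get(self.superroot, "x") is not None:
            raise TreeError("superroot must have no parent")
        n_sr_children = len(self.children[self.superroot])
        if not (1 <= n_sr_children <= 2):
            raise TreeError("superroot must have one child "
                            "(plus at most an outgroup chain)")
        if n_sr_children == 2 and not (
                set(self.children[self.superroot]) & self.outgroup):
            raise TreeError("second superroot child must be an outgroup tube")
        seen = set()
        for v in self.preorder():
            if v in seen:
                raise TreeError("cycle detected")
            seen.add(v)
            cs = self.children.get(v, [])
            if len(cs) == 1 and v != self.superroot and \
                    v not in self.subdivision and v not in self.outgroup:
                raise TreeError(f"vertex {v} has exactly one child")
            if not cs and v not in self.labels and v not in self.outgroup:
                raise TreeError(f"leaf {v} has no label")
            for c in cs:
                if self.parent.get(c) != v:
                    raise TreeError("parent/child tables inconsistent")
        if seen != set(self.children):
            raise TreeError("unreachable vertices present")

    # -- basic queries ---------------------------------------------------

    @property
    def root(self):
        for c in self.children[self.superroot]:
            if c not in self.outgroup:
                return c
        raise TreeError("no root")

    def is_leaf(self, v):
        return not self.children[v]

    def vertices(self):
        return list(self.children)

    def leaves(self):
        return [v for v in self.postorder() if self.is_leaf(v)]

    def species_of(self, v):
        label = self.labels[v]
        return label.rsplit("@", 1)[-1] if "@" in label else label

    def species_set(self):
        return frozenset(self.species_of(v) for v in self.labels)

    @property
    def is_binary(self):
        return all(len(self.children[v]) == 2 for v in self.children
                   if v != self.superroot and not self.is_leaf(v)
                   and v not in self.subdivision and v not in self.outgroup)

    # -- traversals ------------------------------------------------------

    def preorder(self, start=None) -> Iterator[int]:
        stack = [self.superroot if start is None else start]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children[v]))

    def postorder(self, start=None) -> Iterator[int]:
        out = list(self.preorder(start))
        return iter(reversed(out))

    # -- natural order ---------------------------------------------------

    def depth(self, v):
        if self._depth is None:
            d = {self.superroot: 0}
            for u in self.preorder():
                for c in self.children[u]:
                    d[c] = d[u] + 1
            self._depth = d
        return self._depth[v]

    def is_weak_ancestor(self, u, v):
        """True iff u lies on the path superroot..v (u >= v)."""
        while v is not None and self.depth(v) >= self.depth(u):
            if v == u:
                return True
            v = self.parent[v]
        return False

    # -- clades ----------------------------------------------------------

    def clade(self, v) -> frozenset:
        if self._clades is None:
            clades = {}
            for u in self.postorder():
                if self.is_leaf(u):
                    clades[u] = (frozenset() if u in self.outgroup
                                 else frozenset([self.species_of(u)]))
                else:
                    s = frozenset()
                    for c in self.children[u]:
                        s |= clades[c]
                    clades[u] = s
            self._clades = clades
        if v not in self._clades:
            raise TreeError(f"unknown vertex {v!r}")
        return self._clades[v]

    def copy(self):
        return RootedTree(self.parent, self.children, self.superroot,
                          self.labels, self.subdivision, self.outgroup,
                          validate=False)

    def __repr__(self):
        return f"RootedTree({write_newick(self)!r})"


@dataclass
class SlicedSpeciesTree:
    """Binary species tree with subdivision vertices and a time slice
    (rank) per tube; lower tubes never have a smaller rank.  Under the
    uniform-depth policy every rank forms a full cut of the tree and all
    leaf tubes share the last rank."""

    tree: RootedTree
    rank_of: dict
    outgroup_tubes: frozenset = frozenset()

    @property
    def n_slices(self):
        return max(self.rank_of.values()) + 1

    def tubes(self):
        """All tubes (non-superroot vertices), ordered by decreasing rank
        then vertex id."""
        ts = [v for v in self.tree.children if v != self.tree.superroot]
        ts.sort(key=lambda v: (-self.rank_of[v], v))
        return ts

    def same_slice(self, d1, d2):
        """The relation d1 ~ d2: distinct tubes of one time slice."""
        return d1 != d2 and self.rank_of[d1] == self.rank_of[d2]


@dataclass
class CladeFamily:
    """A family P of candidate clades over a species universe V0."""

    universe: frozenset
    members: set = field(default_factory=set)

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        self.members = {frozenset(m) for m in self.members}
        for m in self.members:
            if not m or not m <= self.universe:
                raise TreeError("clade family member outside the universe")

    def add(self, clade):
        clade = frozenset(clade)
        if not clade or not clade <= self.universe:
            raise TreeError("clade outside the universe")
        self.members.add(clade)

    def with_singletons(self):
        fam = CladeFamily(self.universe, set(self.members))
        for s in self.universe:
            fam.members.add(frozenset([s]))
        return fam

    @classmethod
    def from_gene_trees(cls, gene_trees):
        """Default family: all clades of the gene trees, all singletons,
        and the full universe."""
        universe = frozenset().union(*(g.species_set() for g in gene_trees))
        fam = cls(universe)
        for g in gene_trees:
            for v in g.children:
                if v != g.superroot:
                    fam.members.add(g.clade(v))
        fam.members.add(universe)
        return fam.with_singletons()


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str, role: str = "gene") -> RootedTree:
    """Parse a rooted Newick string into a :class:`RootedTree`.

    Branch lengths are parsed and ignored.  ``role='species'`` additionally
    requires pairwise-distinct leaf labels.
    """
    if role not in ("gene", "species"):
        raise TreeError(f"unknown role {role!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(node):
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise TreeError("leaf without a label")
            return node.taxon.label
        return [convert(c) for c in node.child_nodes()]

    seed = dtree.seed_node
    if seed.is_leaf():
        nested = convert(seed)
    else:
        nested = [convert(c) for c in seed.child_nodes()]
        if len(nested) == 1:
            nested = nested[0]
    tree = RootedTree.from_nested(nested)
    if role == "species":
        labels = list(tree.labels.values())
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate species leaf label(s): {sorted(dupes)}")
    return tree


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick.  The superroot, subdivision vertices and the
    outgroup chain are suppressed."""

    def fmt(v):
        while len(tree.children[v]) == 1:  # subdivision / scenario vertex
            v = tree.children[v][0]
        if tree.is_leaf(v):
            return tree.labels[v]
        parts = [fmt(c) for c in tree.children[v] if c not in tree.outgroup]
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Clades, LCA, pruning
# ---------------------------------------------------------------------------

def clade_of(tree: RootedTree, v) -> frozenset:
    """The set (not multiset) of species names at the leaves weakly below v."""
    return tree.clade(v)


def lca_of(tree: RootedTree, labels: Iterable[str]):
    """The unique minimal vertex whose clade contains ``labels``
    (species names; the tree's leaf labels must cover them)."""
    labels = frozenset(labels)
    if not labels:
        raise TreeError("empty label set")
    leaf_by_species = {}
    for leaf in tree.labels:
        leaf_by_species.setdefault(tree.species_of(leaf), leaf)
    try:
        nodes = [leaf_by_species[s] for s in sorted(labels)]
    except KeyError as exc:
        raise TreeError(f"label {exc.args[0]!r} absent from tree") from exc

    def lca2(a, b):
        while a != b:
            if tree.depth(a) >= tree.depth(b):
                a = tree.parent[a]
            else:
                b = tree.parent[b]
        return a

    node = nodes[0]
    for other in nodes[1:]:
        node = lca2(node, other)
    return node


def prune_to(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Remove every maximal subtree whose clade is disjoint from ``keep``,
    then suppress single-child chains.  The result's clade is the
    intersection of the tree's clade with ``keep``."""
    keep = frozenset(keep)
    if not keep & tree.clade(tree.root):
        raise TreeError("pruning would remove every leaf")

    def build(v):
        if tree.is_leaf(v):
            return tree.labels[v] if tree.species_of(v) in keep else None
        parts = [p for p in (build(c) for c in tree.children[v])
                 if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return parts

    nested = build(tree.root)
    return RootedTree.from_nested(nested)


# ---------------------------------------------------------------------------
# Time slices
# ---------------------------------------------------------------------------

def assign_time_slices(S: RootedTree, policy: str = "uniform-depth",
                       with_outgroup: bool = False) -> SlicedSpeciesTree:
    """Insert subdivision vertices so every root-to-leaf path crosses the
    same number of tubes h, and rank tubes by depth (root tube = rank 0,
    leaf tubes = rank h-1).  With ``with_outgroup`` an auxiliary chain of h
    outgroup tubes is attached beside the root tube, one tube per slice.
    """
    if policy != "uniform-depth":
        raise TreeError(f"unknown slice policy {policy!r}")
    if not S.is_binary:
        raise TreeError("species tree must be binary for slicing")

    # tube-depth of leaf tubes (tubes on the path from superroot, inclusive)
    tube_depth = {}
    for v in S.preorder():
        if v == S.superroot:
            tube_depth[v] = 0
        else:
            tube_depth[v] = tube_depth[S.parent[v]] + 1
    h = max(tube_depth[l] for l in S.labels)

    parent = dict(S.parent)
    children = {v: list(cs) for v, cs in S.children.items()}
    labels = dict(S.labels)
    subdivision = set()
    outgroup = set()
    next_id = max(children) + 1
    rank = {}
    for v in S.children:
        if v != S.superroot:
            rank[v] = tube_depth[v] - 1

    # pad each short leaf edge with subdivision vertices just above the leaf
    for leaf in list(S.labels):
        deficit = h - tube_depth[leaf]
        upper = parent[leaf]
        for k in range(deficit):
            w = next_id
            next_id += 1
            subdivision.add(w)
            children[upper] = [w if c == leaf else c for c in children[upper]]
            parent[w] = upper
            children[w] = [leaf]
            parent[leaf] = w
            rank[w] = tube_depth[leaf] - 1 + k
            upper = w
        if deficit:
            rank[leaf] = h - 1

    if with_outgroup:
        upper = S.superroot
        for r in range(h):
            w = next_id
            next_id += 1
            outgroup.add(w)
            children[upper].append(w)
            parent[w] = upper
            children[w] = []
            rank[w] = r
            upper = w

    tree = RootedTree(parent, children, S.superroot, labels,
                      subdivision=frozenset(subdivision),
                      outgroup=frozenset(outgroup))
    sliced = SlicedSpeciesTree(tree, rank, frozenset(outgroup))
    # sanity: monotone rank condition
    for v in tree.children:
        if v in (tree.superroot,):
            continue
        p = tree.parent[v]
        if p != tree.superroot and p in rank and rank[v] < rank[p]:
            raise TreeError("rank ordering violated")
    return sliced


# ---------------------------------------------------------------------------
# Order helpers on the united set of vertices and tubes of one tree
# ---------------------------------------------------------------------------
# A location is ("v", x) for vertex x or ("t", x) for the tube entering x.
# The tube into x lies strictly between x and its parent vertex.

def loc_weak_leq(tree: RootedTree, a, b) -> bool:
    """a <= b in the natural order on vertices and tubes."""
    ka, xa = a
    kb, xb = b
    if ka == "t" and kb == "v":
        return xa != xb and tree.is_weak_ancestor(xb, xa)
    return tree.is_weak_ancestor(xb, xa)


def loc_strict_less(tree: RootedTree, a, b) -> bool:
    return a != b and loc_weak_leq(tree, a, b)


def loc_comparable(tree: RootedTree, a, b) -> bool:
    return loc_weak_leq(tree, a, b) or loc_weak_leq(tree, b, a)
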