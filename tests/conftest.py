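"""Shared helpers: random topologies, canonical forms, instance censuses."""

import itertools
import random

import pytest

from treerec.trees import RootedTree


def insert_everywhere(nested, lab):
    out = [[nested, lab]]
    if isinstance(nested, list):
        left, right = nested
        out += [[l, right] for l in insert_everywhere(left, lab)]
        out += [[left, r] for r in insert_everywhere(right, lab)]
    return out


def random_topology(labels, rng: random.Random) -> RootedTree:
    labs = list(labels)
    rng.shuffle(labs)
    nested = labs[0]
    for lab in labs[1:]:
        opts = insert_everywhere(nested, lab)
        nested = opts[rng.randrange(len(opts))]
    return RootedTree.from_nested(nested)


def all_topologies(labels):
    labels = sorted(labels)
    structs = [labels[0]]
    for lab in labels[1:]:
        structs = [s for t in structs for s in insert_everywhere(t, lab)]
    return [RootedTree.from_nested(s) for s in structs]


def canon(t: RootedTree):
    """Order-insensitive canonical form for topology comparison."""

    def rec(v):
        if t.is_leaf(v):
            return t.labels[v]
        return tuple(sorted((rec(c) for c in t.children[v]), key=str))

    return rec(t.root)


def gene_leaf_multisets(species, max_leaves):
    """All gene-leaf label multisets over the species (paralogs allowed),
    sizes 2..max_leaves; duplicated species get id@species labels."""
    species = sorted(species)
    for k in range(2, max_leaves + 1):
        for combo in itertools.combinations_with_replacement(species, k):
            counts = {}
            labels = []
            for s in combo:
                counts[s] = counts.get(s, 0) + 1
                labels.append(f"g{counts[s]}@{s}" if combo.count(s) > 1
                              else s)
            yield labels


@pytest.fixture
def rng():
    return random.Random(20240917)
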