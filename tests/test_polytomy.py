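"""Polytomy resolution: entering relation, bundles, paralogous
binarization, Par', and the bundle-count supertree recursion."""

import pytest

from treerec.polytomy import (binarization_step, bundles_for,
                              enumerate_candidate_binarizations,
                              enters_tube, is_paralogous_binarization,
                              par_prime, paralogous_binarization,
                              phase1_polytomous, poly_q_counts)
from treerec.reconcile import (EventCosts, compute_alpha, infer_events,
                               par_count)
from treerec.supertree import phase1, q_counts
from treerec.trees import CladeFamily, TreeError, parse_newick, write_newick

from conftest import canon, random_topology

COSTS = EventCosts(div=0.5, dup=2, loss_explicit=1, loss_implicit=0.25)


def species_vertex(S, clade):
    return next(v for v in S.vertices() if v != S.superroot
                and S.clade(v) == frozenset(clade))


class TestEntersTube:
    def test_leaf_edge_enters_ancestor_tube(self):
        G = parse_newick("((a,b),c);")
        S = parse_newick("((a,c),b);", "species")
        leaf_a = next(v for v in G.labels if G.labels[v] == "a")
        assert enters_tube(G, S, leaf_a, species_vertex(S, "ac"))

    def test_equal_endpoint_tubes_enter_nothing(self):
        # both termini of a paralog edge sit in the same leaf tube
        G = parse_newick("(x@a,y@a);")
        S = parse_newick("(a,b);", "species")
        for e in G.labels:  # edges into the two paralog leaves
            for d in S.vertices():
                if d != S.superroot:
                    assert not enters_tube(G, S, e, d)

    def test_superroot_edge_mapped_to_root_tube_enters_nothing(self):
        G = parse_newick("(a,b);")
        S = parse_newick("(a,b);", "species")
        for d in S.vertices():
            if d == S.superroot:
                continue
            assert not enters_tube(G, S, G.root, d)


class TestBundles:
    def test_two_singleton_bundles(self):
        G = parse_newick("((a,b),c);")
        S = parse_newick("((a,c),b);", "species")
        bs = bundles_for(G, S, species_vertex(S, "ac"))
        assert len(bs) == 2
        assert all(len(b.edges) == 1 for b in bs)
        assert len({b.parent_vertex for b in bs}) == 2

    def test_polytomy_single_bundle_of_two(self):
        G = parse_newick("(a,b,c);")
        S = parse_newick("((a,b),c);", "species")
        bs = bundles_for(G, S, species_vertex(S, "ab"))
        assert len(bs) == 1 and len(bs[0].edges) == 2
        assert bs[0].parent_vertex == G.root

    def test_no_species_below_empty(self):
        G = parse_newick("(a,b);")
        S = parse_newick("((a,b),(c,d));", "species")
        assert bundles_for(G, S, species_vertex(S, "cd")) == []


class TestBinarizationStep:
    def test_three_way_split(self):
        t = parse_newick("(a,b,c);")
        kids = t.children[t.root]
        A = [k for k in kids if t.labels.get(k) in ("a", "b")]
        B = [k for k in kids if t.labels.get(k) == "c"]
        assert write_newick(binarization_step(t, t.root, A, B)) == \
            "((a,b),c);"

    def test_singleton_part_skips_new_vertex(self):
        t = parse_newick("(a,b,c,d);")
        kids = t.children[t.root]
        A = [k for k in kids if t.labels.get(k) == "a"]
        B = [k for k in kids if k not in A]
        out = binarization_step(t, t.root, A, B)
        assert write_newick(out) == "(a,(b,c,d));"

    def test_binary_vertex_rejected(self):
        t = parse_newick("(a,b);")
        with pytest.raises(TreeError):
            binarization_step(t, t.root, [t.children[t.root][0]],
                              [t.children[t.root][1]])


class TestParalogousBinarization:
    @pytest.mark.parametrize("g,s,expect", [
        ("((a,b),c);", "((a,b),c);", "((a,b),c);"),   # binary unchanged
        ("(a,b,c);", "((a,b),c);", "((a,b),c);"),
        ("(x@a,y@a,b);", "(a,b);", "((x@a,y@a),b);"),
    ])
    def test_examples(self, g, s, expect):
        out = paralogous_binarization(parse_newick(g),
                                      parse_newick(s, "species"))
        assert canon(out) == canon(parse_newick(expect))

    @pytest.mark.parametrize("g,s", [
        ("(a,b,c);", "((a,b),c);"),
        ("(a,b,c,d);", "((a,b),(c,d));"),
        ("(x@a,y@a,b);", "(a,b);"),
        ("((a,b,c),d);", "(((a,b),c),d);"),
        ("(x@a,y@a,z@a);", "(a,b);"),
        ("((a,c),b,d);", "((a,b),(c,d));"),
        ("(a,b,(c,d,e));", "(((a,b),c),(d,e));"),
    ])
    def test_minimality_and_cost_invariance(self, g, s):
        """G## realizes, per tube, the minimum entering-edge count over
        all candidate binarizations, and every binarization in the
        paralogous class has the same embedding cost."""
        G = parse_newick(g)
        S = parse_newick(s, "species")
        gg = paralogous_binarization(G, S)
        assert is_paralogous_binarization(gg, G, S)
        p_counts = {d: len(bundles_for(G, S, d)) for d in S.vertices()
                    if d != S.superroot}
        per_tube_min = None
        class_costs = set()
        for cand in enumerate_candidate_binarizations(G):
            alpha = compute_alpha(cand, S)
            counts = {d: sum(1 for e in cand.vertices()
                             if e != cand.superroot
                             and enters_tube(cand, S, e, d, alpha))
                      for d in p_counts}
            if per_tube_min is None:
                per_tube_min = counts
            else:
                per_tube_min = {d: min(per_tube_min[d], counts[d])
                                for d in counts}
            if is_paralogous_binarization(cand, G, S):
                class_costs.add(infer_events(cand, S, alpha,
                                             COSTS).total_cost)
        assert p_counts == per_tube_min
        assert len(class_costs) == 1
        assert infer_events(gg, S, compute_alpha(gg, S),
                            COSTS).total_cost in class_costs

    def test_bundle_parent_bijection(self):
        """In G## every bundle of G has exactly one parent edge entering
        its tube, and every entering edge is some bundle's parent."""
        for g, s in [("(a,b,c,d);", "((a,b),(c,d));"),
                     ("((a,c),b,d);", "((a,b),(c,d));")]:
            G = parse_newick(g)
            S = parse_newick(s, "species")
            gg = paralogous_binarization(G, S)
            alpha = compute_alpha(gg, S)
            for d in S.vertices():
                if d == S.superroot:
                    continue
                n_bundles = len(bundles_for(G, S, d))
                n_entering = sum(1 for e in gg.vertices()
                                 if e != gg.superroot
                                 and enters_tube(gg, S, e, d, alpha))
                assert n_bundles == n_entering


class TestParPrime:
    def test_triple_paralog(self):
        assert par_prime(parse_newick("(x@a,y@a,z@a);"),
                         parse_newick("(a,b);", "species"), "a") == 2

    def test_no_paralogs_zero(self):
        assert par_prime(parse_newick("((a,b),c);"),
                         parse_newick("((a,b),c);", "species"), "a") == 0

    def test_binary_equals_par(self, rng):
        for _ in range(20):
            S = random_topology("abc", rng)
            species = [rng.choice("abc") for _ in range(rng.randint(2, 5))]
            G = random_topology([f"g{i}@{x}" for i, x in
                                 enumerate(species)], rng)
            for s in "abc":
                assert par_prime(G, S, s) == par_count(G, s)

    def test_matches_explicit_binarization(self):
        G = parse_newick("(x@a,y@a,z@a,b);")
        S = parse_newick("(a,b);", "species")
        gg = paralogous_binarization(G, S)
        inv = infer_events(gg, S, compute_alpha(gg, S), COSTS)
        leaf_a = next(v for v in S.labels if S.labels[v] == "a")
        dups_in_a = sum(1 for _, d in inv.duplications if d == leaf_a)
        assert dups_in_a == par_prime(G, S, "a")

    def test_unknown_species(self):
        with pytest.raises(TreeError):
            par_prime(parse_newick("(a,b);"),
                      parse_newick("(a,b);", "species"), "z")


class TestPolyQCounts:
    def test_flat_triple(self):
        q = poly_q_counts([parse_newick("(a,b,c);")], {"a", "b"}, {"c"})
        assert (q.n, q.n1, q.n2, q.k) == (1, 1, 1, 1)
        assert (q.n1p, q.n2p, q.kp) == (1, 1, 1)
        assert (q.n1pp, q.n2pp, q.kpp) == (0, 0, 0)

    def test_disjoint_species_all_zero(self):
        q = poly_q_counts([parse_newick("(a,b,c);")], {"x"}, {"y"})
        assert (q.n, q.n1, q.n2, q.k) == (0, 0, 0, 0)

    def test_matches_qcounts_on_binary_inputs(self, rng):
        """On binary gene trees the bundle-count cost term reproduces the
        q-count cost term exactly."""
        for _ in range(100):
            n = rng.choice([3, 4, 5])
            V0 = "abcde"[:n]
            Gjs = [random_topology(rng.sample(V0, rng.randint(2, n)), rng)
                   for _ in range(2)]
            full = sorted(set().union(*(g.species_set() for g in Gjs)))
            if len(full) < 2:
                continue
            k = rng.randint(1, len(full) - 1)
            V1 = frozenset(rng.sample(full, k))
            V2 = frozenset(full) - V1
            q1, q2, q3p, q3pp = q_counts(Gjs, V1, V2)
            q = poly_q_counts(Gjs, V1, V2)
            for w in (COSTS, EventCosts()):
                e9 = (w.div * q1 + w.dup * q2 + w.loss_explicit * q3p
                      + w.loss_implicit * q3pp)
                e12 = (w.div * q.k + w.dup * (q.n1 + q.n2 - q.n - q.k)
                       + w.loss_explicit * (q.n1p + q.n2p - 2 * q.kp)
                       + w.loss_implicit * (q.n1pp + q.n2pp - 2 * q.kpp))
                assert e9 == pytest.approx(e12)


class TestPhase1Polytomous:
    def test_binary_inputs_identical_tables(self, rng):
        for _ in range(10):
            n = rng.choice([3, 4])
            V0 = "abcd"[:n]
            Gjs = [random_topology(rng.sample(V0, rng.randint(2, n)), rng)
                   for _ in range(2)]
            fam = CladeFamily.from_gene_trees(Gjs)
            t_bin = phase1(Gjs, fam, COSTS)
            t_poly = phase1_polytomous(Gjs, fam, COSTS)
            assert set(t_bin.entries) == set(t_poly.entries)
            for V in t_bin.entries:
                assert t_bin.cost(V) == pytest.approx(t_poly.cost(V))

    def test_flat_triple_resolved(self):
        Gp = parse_newick("(a,b,c);")
        fam = CladeFamily(frozenset("abc"),
                          {frozenset("ab"),
                           frozenset("abc")}).with_singletons()
        table = phase1_polytomous([Gp], fam)
        V0 = frozenset("abc")
        assert canon(table.tree(V0)) == canon(parse_newick("((a,b),c);"))
        # cost equals the embedding cost of the explicit binarization
        S = table.tree(V0)
        S = parse_newick(write_newick(S), "species")
        gg = paralogous_binarization(Gp, S)
        direct = infer_events(gg, S, compute_alpha(gg, S),
                              EventCosts()).total_cost
        assert table.cost(V0) == pytest.approx(direct)

    def test_paralog_singleton_uses_par_prime(self):
        table = phase1_polytomous(
            [parse_newick("(x@a,y@a,z@a);")],
            CladeFamily(frozenset("a"), {frozenset("a")}))
        assert table.cost(frozenset("a")) == 2 * EventCosts().dup
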