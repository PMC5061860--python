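"""X-morphisms, folding maps, fibre partitions, quotients, lifting."""

import random

import pytest

from mulfold import canon, synth
from mulfold.core import PseudoMULTree, RootedDAG, tree_as_network, validate
from mulfold.fibration import (
    QuotientError,
    VertexPartition,
    XMorphism,
    lift,
    partition_is_fibration,
    quotient,
    verify_folding_map,
    verify_x_morphism,
)
from mulfold.fold import fold, fold_sequence, guide_tree
from mulfold.unfold import unfold, unfold_star


def _identity_morphism(t):
    return XMorphism({v: v for v in t.tree.vertices},
                     {a: a for a in t.tree.arcs})


class TestVerifyXMorphism:
    def test_fstar_is_a_rooted_morphism(self, N1):
        res = unfold_star(N1)
        rep = verify_x_morphism(res.fstar, res.ustar, N1, rooted=True)
        assert rep.ok

    def test_identity_on_a_tree(self):
        t = synth.random_binary_tree(["a", "b", "c"], 4)
        n = tree_as_network(t)
        f = XMorphism(dict(_identity_morphism(t).vmap),
                      dict(_identity_morphism(t).amap))
        assert verify_x_morphism(f, t, n, rooted=True).ok

    def test_perturbed_arc_image_is_flagged(self, N1):
        res = unfold_star(N1)
        f = XMorphism(dict(res.fstar.vmap), dict(res.fstar.amap))
        some_arc = sorted(f.amap)[0]
        other_image = sorted(set(N1.dag.arcs) - {f.amap[some_arc]})[0]
        f.amap[some_arc] = other_image
        rep = verify_x_morphism(f, res.ustar, N1)
        assert not rep.ok
        assert any("incidence" in v for v in rep.violations)


class TestVerifyFoldingMap:
    def test_fstar_on_random_networks(self):
        for s in range(30):
            n = synth.random_network(x_size=4, reticulations=s % 4, seed=s)
            res = unfold_star(n)
            assert verify_folding_map(res.fstar, res.ustar, n).ok

    def test_identity_on_a_tree_is_a_folding_map(self):
        t = synth.random_binary_tree(["a", "b", "c"], 4)
        assert verify_folding_map(_identity_morphism(t), t,
                                  tree_as_network(t)).ok

    def test_non_unique_lifting_is_detected(self, M2):
        # fold M2 and redirect both root arcs of the guide tree onto the
        # same parallel arc of the quotient: incidence still holds but the
        # lifting at the root fibre stops being unique
        tr = fold(M2)
        q = quotient(tr.guide, tr.partition)
        assert verify_folding_map(q.projection, tr.guide,
                                  q.pre_suppression).ok
        g = XMorphism(dict(q.projection.vmap), dict(q.projection.amap))
        root_arcs = sorted(a for a in g.amap if a[0] == tr.guide.root)
        assert len(root_arcs) == 2
        g.amap[root_arcs[1]] = g.amap[root_arcs[0]]
        rep = verify_folding_map(g, tr.guide, q.pre_suppression)
        assert not rep.ok
        assert rep.lifting_counts or any(
            "surjective" in v for v in rep.violations
        )


class TestPartitionIsFibration:
    def test_guide_partition_of_m1_is_a_fibration(self, M1):
        tr = fold(M1)
        rep = partition_is_fibration(tr.guide, tr.partition)
        assert rep.ok

    def test_guide_partition_of_m2_fails_parallel_property(self, M2):
        tr = fold(M2)
        rep = partition_is_fibration(tr.guide, tr.partition)
        assert not rep.ok
        assert rep.properties["parallel"] is False

    def test_discrete_partition_on_a_tree(self):
        t = synth.random_binary_tree(["a", "b", "c"], 8)
        p = VertexPartition([{v} for v in t.tree.vertices])
        assert partition_is_fibration(t, p).ok

    def test_equivalence_with_quotient_validity(self):
        """Five-property check <=> quotient is a phylogenetic network whose
        projection is a folding map with the given fibres."""
        rng = random.Random(0)
        checked_true = checked_false = 0
        for s in range(60):
            t = synth.random_multree(["a", "b", "c"], dup=rng.randrange(3),
                                     seed=s)
            tg = guide_tree(fold_sequence(t))
            p = VertexPartition.from_codes(tg)
            if rng.random() < 0.5 and len(p.blocks) > 2:
                # perturb: split one block or merge two
                blocks = [set(b) for b in p.blocks]
                if rng.random() < 0.5:
                    big = max(blocks, key=len)
                    if len(big) >= 2:
                        v = sorted(big, key=str)[0]
                        big.discard(v)
                        blocks.append({v})
                else:
                    i, j = rng.sample(range(len(blocks)), 2)
                    blocks[i] |= blocks[j]
                    del blocks[j]
                p = VertexPartition([b for b in blocks if b])
            lhs = partition_is_fibration(tg, p).ok
            try:
                q = quotient(tg, p)
                rhs = (
                    validate(q.network, "phylo_network").ok
                    and not q.suppressed
                    and verify_folding_map(q.projection, tg,
                                           q.pre_suppression).ok
                )
            except QuotientError:
                rhs = False
            assert lhs == rhs, s
            checked_true += lhs
            checked_false += not lhs
        assert checked_true and checked_false


class TestQuotient:
    def test_quotient_of_m1_guide_is_n1(self, M1, N1):
        tr = fold(M1)
        q = quotient(tr.guide, tr.partition)
        assert canon.network_isomorphic(q.network, N1)

    def test_discrete_partition_gives_the_tree_back(self):
        t = synth.random_binary_tree(["a", "b", "c", "d"], 2)
        q = quotient(t, VertexPartition([{v} for v in t.tree.vertices]))
        assert canon.network_isomorphic(q.network, tree_as_network(t))

    def test_m2_quotient_has_multiplicity_two(self, M2):
        tr = fold(M2)
        q = quotient(tr.guide, tr.partition)
        root = q.network.dag.root
        assert len(q.network.dag.out_arcs(root)) == 2
        assert len(q.network.dag.children(root)) == 1

    def test_representative_dependence_raises(self, M1):
        # {p, q} block with asymmetric child blocks: the arc multiplicity
        # depends on the chosen representative
        p = VertexPartition([
            {"rho"}, {"p", "q"}, {"a", "c1"}, {"b"}, {"c2"},
        ])
        with pytest.raises(QuotientError):
            quotient(M1, p)


class TestLift:
    def test_lift_of_fstar_through_itself_is_identity(self, N1):
        res = unfold_star(N1)
        g = lift(res.fstar, res.fstar, res.ustar, res.ustar, N1)
        assert all(v == u for v, u in g.vmap.items())

    def test_lift_embeds_a_displayed_tree_into_ustar(self, N1):
        # T' = subdivision of ((a,c),b) following the reconciliation into N1
        tp = PseudoMULTree(
            RootedDAG(
                [("R", "U"), ("R", "W"), ("W", "B"), ("U", "A"),
                 ("U", "Rr"), ("Rr", "C")],
                root="R",
            ),
            {"A": "a", "B": "b", "C": "c"},
        )
        g = XMorphism(
            {"R": "rho", "U": "u", "W": "v", "A": "a", "B": "b",
             "Rr": "r", "C": "c"},
            {
                ("R", "U", 0): ("rho", "u", 0),
                ("R", "W", 0): ("rho", "v", 0),
                ("W", "B", 0): ("v", "b", 0),
                ("U", "A", 0): ("u", "a", 0),
                ("U", "Rr", 0): ("u", "r", 0),
                ("Rr", "C", 0): ("r", "c", 0),
            },
        )
        assert verify_x_morphism(g, tp, N1, rooted=True).ok
        res = unfold_star(N1)
        gt = lift(g, res.fstar, tp, res.ustar, N1)
        # contract: f o g~ = g, arc by arc
        for a, ga in g.amap.items():
            assert res.fstar.amap[gt.amap[a]] == ga
        for v, gv in g.vmap.items():
            assert res.fstar.vmap[gt.vmap[v]] == gv

    def test_composition_contract_on_random_networks(self):
        for s in range(20):
            n = synth.random_network(x_size=4, reticulations=s % 3, seed=s)
            res = unfold_star(n)
            gt = lift(res.fstar, res.fstar, res.ustar, res.ustar, n)
            assert all(
                res.fstar.amap[gt.amap[a]] == res.fstar.amap[a]
                for a in res.ustar.tree.arcs
            )

    def test_rooted_lift_is_pointwise_unique(self, N1):
        """Exhaustively try alternative images: any deviation breaks either
        the morphism property or the composition contract."""
        res = unfold_star(N1)
        gt = lift(res.fstar, res.fstar, res.ustar, res.ustar, N1)
        lift_index = {}
        for a, fa in res.fstar.amap.items():
            lift_index[(a[0], fa)] = a
        # at every vertex of T', the next arc image is forced
        for v in res.ustar.tree.vertices:
            for a in res.ustar.tree.out_arcs(v):
                candidates = [
                    ta for ta in res.ustar.tree.arcs
                    if ta[0] == gt.vmap[v]
                    and res.fstar.amap[ta] == res.fstar.amap[a]
                ]
                assert candidates == [gt.amap[a]]

    def test_corollary2_folding_map_forces_ustar(self, M1, N1):
        """Any folding map T' -> N exhibits T' as the unfolding U*(N)."""
        tr = fold(M1)
        q = quotient(tr.guide, tr.partition)
        n = q.network
        assert validate(n, "phylo_network").ok
        # the projection onto the *unsuppressed* quotient is a folding map
        g = q.projection
        assert verify_folding_map(g, tr.guide, q.pre_suppression).ok
        res = unfold_star(q.pre_suppression)
        gt = lift(g, res.fstar, tr.guide, res.ustar, q.pre_suppression)
        # g~ is a bijection on vertices -> T' ~ U*(N)
        assert len(set(gt.vmap.values())) == len(gt.vmap)
        assert len(res.ustar.tree) == len(tr.guide.tree)
        assert canon.multree_isomorphic(tr.guide, res.ustar)
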