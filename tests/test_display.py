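"""Display testing, the weak-display DP, reconciliations, HangLeaves."""

import random

import pytest

from mulfold import canon, synth, treeio
from mulfold.core import GraphError, properties, validate, vertex_class
from mulfold.display import (
    displays_bruteforce,
    displays_in_multree,
    hang_leaves,
    reconciliation,
    stable_instance,
    verify_reconciliation,
    weakly_displays,
)
from mulfold.stability import is_stable
from mulfold.unfold import unfold


def tree(newick: str):
    return treeio.read(newick, "mul_newick")


@pytest.fixture
def t_acb():
    return tree("((a,c),b);")


@pytest.fixture
def t_abc():
    return tree("((a,b),c);")


class TestDisplaysBruteforce:
    def test_n1_displays_one_of_its_two_trees(self, N1, t_acb, t_abc):
        ok, witness = displays_bruteforce(N1, t_acb)
        assert ok and witness is not None
        assert not displays_bruteforce(N1, t_abc)[0]

    def test_a_tree_displays_itself(self):
        t = synth.random_binary_tree(["a", "b", "c", "d"], 6)
        from mulfold.core import tree_as_network

        assert displays_bruteforce(tree_as_network(t), t)[0]

    def test_witness_cleans_to_the_tree(self, N1, t_acb):
        ok, witness = displays_bruteforce(N1, t_acb)
        from mulfold.display import _clean_to_tree

        cleaned = _clean_to_tree(witness.dag, witness.leaf_label)
        assert canon.multree_isomorphic(cleaned, t_acb)


class TestDisplaysInMultree:
    def test_m1_displays_acb_not_abc(self, M1, t_acb, t_abc):
        assert displays_in_multree(M1, t_acb)
        assert not displays_in_multree(M1, t_abc)

    def test_a_tree_displays_itself(self):
        t = synth.random_binary_tree(["a", "b", "c", "d"], 8)
        assert displays_in_multree(t, t)


class TestWeaklyDisplays:
    def test_n1_answers_match_the_multree_oracle(self, N1, t_acb, t_abc):
        assert weakly_displays(N1, t_acb)[0]
        assert not weakly_displays(N1, t_abc)[0]

    def test_on_trees_weak_display_is_isomorphism(self):
        from mulfold.core import tree_as_network

        t1 = synth.random_binary_tree(["a", "b", "c", "d"], 3)
        t2 = synth.random_binary_tree(["a", "b", "c", "d"], 12)
        n1 = tree_as_network(t1)
        assert weakly_displays(n1, t1)[0]
        assert weakly_displays(n1, t2)[0] == canon.multree_isomorphic(t1, t2)

    def test_agreement_with_unfolded_oracle(self):
        for s in range(80):
            rng = random.Random(s)
            n = synth.random_network(x_size=4, reticulations=rng.randrange(4),
                                     seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(4)], s + 999)
            got, _ = weakly_displays(n, t)
            assert got == displays_in_multree(unfold(n), t)

    def test_displayed_implies_weakly_displayed(self):
        for s in range(40):
            n = synth.random_network(x_size=4, reticulations=s % 3, seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(4)], s + 5)
            if displays_bruteforce(n, t)[0]:
                assert weakly_displays(n, t)[0]

    def test_tau_monotone_along_ancestors(self):
        for s in range(25):
            n = synth.random_network(x_size=4, reticulations=s % 4, seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(4)], s)
            _, table = weakly_displays(n, t)
            for (v, u), val in table.tau.items():
                if val:
                    for p in n.dag.parents(u):
                        assert table.tau[(v, p)] == 1

    def test_update_count_is_linear_in_mnk(self):
        for s in range(25):
            n = synth.random_network(x_size=5, reticulations=s % 5, seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(5)], s)
            _, table = weakly_displays(n, t)
            assert table.updates <= 2 * table.m * table.n * table.k

    def test_non_binary_guest_tree_rejected(self, N1):
        from mulfold.core import MULTree, RootedDAG

        t = MULTree(
            RootedDAG([("r", "a"), ("r", "b"), ("r", "c")], root="r"),
            {"a": "a", "b": "b", "c": "c"},
        )
        with pytest.raises(GraphError):
            weakly_displays(N1, t)


class TestReconciliation:
    def test_extracted_map_for_n1(self, N1, t_acb):
        rec = reconciliation(N1, t_acb)
        assert rec is not None
        rep = verify_reconciliation(rec, t_acb, N1)
        assert rep.ok and rep.locally_separated
        # r lands on tree vertices / the root only
        assert set(rec.r.values()) <= {"rho", "u", "v", "a", "b", "c"}

    def test_absent_when_not_weakly_displayed(self, N1, t_abc):
        assert reconciliation(N1, t_abc) is None

    def test_identity_reconciliation_on_a_tree(self):
        from mulfold.core import tree_as_network

        t = synth.random_binary_tree(["a", "b", "c"], 77)
        rec = reconciliation(tree_as_network(t), t)
        assert rec is not None
        assert all(len(p) == 1 for p in rec.paths.values())

    def test_every_positive_answer_yields_a_valid_witness(self):
        hits = 0
        for s in range(60):
            n = synth.random_network(x_size=4, reticulations=s % 4, seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(4)], s + 31)
            rec = reconciliation(n, t)
            assert (rec is not None) == weakly_displays(n, t)[0]
            if rec is not None:
                hits += 1
                rep = verify_reconciliation(rec, t, n)
                assert rep.ok and rep.locally_separated
        assert hits >= 5

    def test_truncated_path_is_flagged(self, N1, t_acb):
        rec = reconciliation(N1, t_acb)
        arc = sorted(rec.paths)[0]
        rec.paths[arc] = []
        rep = verify_reconciliation(rec, t_acb, N1)
        assert not rep.ok

    def test_shared_initial_arc_breaks_local_separation(self, N1, t_acb):
        rec = reconciliation(N1, t_acb)
        root_arcs = sorted(a for a in rec.paths if a[0] == t_acb.root)
        assert len(root_arcs) == 2
        rec.paths[root_arcs[1]] = list(rec.paths[root_arcs[0]])
        rep = verify_reconciliation(rec, t_acb, N1)
        assert not rep.ok


class TestHangLeaves:
    def test_gadget_counts_and_classes(self, N1, t_acb):
        n2, r2 = hang_leaves(N1, t_acb, "u")
        assert len(n2.dag) == len(N1.dag) + 5
        assert len(n2.dag.arcs) == len(N1.dag.arcs) + 6
        assert len(r2.tree) == len(t_acb.tree) + 4
        assert len(r2.tree.arcs) == len(t_acb.tree.arcs) + 4
        assert vertex_class(n2.dag, "q[u]") == "reticulation"
        assert vertex_class(n2.dag, "p[u]") == "internal_tree"
        assert n2.dag.root == "rho[u]"
        assert len(n2.X) == len(N1.X) + 2 and n2.X == r2.X

    def test_repeated_application_with_fresh_labels(self, N1, t_acb):
        n2, r2 = hang_leaves(N1, t_acb, "u")
        n3, r3 = hang_leaves(n2, r2, "v")
        assert len(n3.X) == len(N1.X) + 4
        assert validate(n3, "phylo_network").ok
        assert validate(r3, "mul_tree").ok

    def test_label_collision_raises(self, N1, t_acb):
        with pytest.raises(GraphError):
            hang_leaves(N1, t_acb, "u", names=("a", "zz", "p9", "q9", "r9"))


class TestStableInstance:
    def test_n1_reduction_grows_x_to_nine(self, N1, t_acb):
        ns, ts = stable_instance(N1, t_acb)
        assert len(ns.X) == 9 and ns.X == ts.X
        p = properties(ns)
        assert p.binary and p.compressed and p.tree_sibling
        assert validate(ns, "phylo_network").ok

    def test_reduced_network_is_stable(self, N1, t_acb):
        ns, _ = stable_instance(N1, t_acb)
        assert is_stable(ns).stable_direct

    def test_display_equivalence_both_polarities(self, N1, t_acb, t_abc):
        for t in (t_acb, t_abc):
            want = displays_bruteforce(N1, t)[0]
            ns, ts = stable_instance(N1, t)
            assert displays_bruteforce(ns, ts)[0] == want

    def test_reduction_correctness_on_random_instances(self):
        for s in range(12):
            n = synth.random_network(x_size=4, reticulations=2, seed=s)
            t = synth.random_binary_tree([f"t{i}" for i in range(4)], s + 400)
            d0 = displays_bruteforce(n, t)[0]
            ns, ts = stable_instance(n, t)
            p = properties(ns)
            assert p.binary and p.compressed and p.tree_sibling
            assert is_stable(ns).stable_direct
            assert displays_bruteforce(ns, ts)[0] == d0
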