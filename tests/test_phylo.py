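import numpy as np
import pytest

import dendropy
from dendropy.calculate import treecompare

from viroclade.align import MSA
from viroclade.phylo import (
    DistanceMatrix,
    bootstrap_support,
    collapse_low_support,
    delineate_clades,
    leaf_names,
    neighbor_joining,
    p_distance_matrix,
    random_tree,
    read_newick,
    rf_distance,
    rf_max,
    rf_permutation_test,
    root_with_outgroup,
    write_newick,
)


def dendropy_rf(t1, t2) -> int:
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return treecompare.symmetric_difference(d1, d2)


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(MSA([("a", "ACGT"), ("b", "ACGT")]))
        assert dm.matrix[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        dm = p_distance_matrix(MSA([("a", "AAAA"), ("b", "AAAT")]))
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_disjoint_coverage_flagged(self):
        dm = p_distance_matrix(MSA([("a", "AC--"), ("b", "--GT")]))
        assert dm.matrix[0, 1] == 1.0
        assert frozenset(("a", "b")) in dm.no_overlap

    def test_gap_columns_excluded(self):
        dm = p_distance_matrix(MSA([("a", "A-CT"), ("b", "AGCA")]))
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)


class TestNeighborJoining:
    # path distances of the additive tree ((A:1,B:2):1,(C:3,D:4))
    QUARTET = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )

    def test_quartet_topology_and_branch_lengths(self):
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), self.QUARTET))
        for x in "ABCD":
            for y in "ABCD":
                if x < y:
                    want = self.QUARTET["ABCD".index(x), "ABCD".index(y)]
                    assert tree.distance(x, y) == pytest.approx(want, abs=1e-9)
        ref = read_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert rf_distance(tree, ref) == 0

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(list("ABC"), D))
        assert len(tree.root.clades) == 3
        assert tree.distance("A", "B") == pytest.approx(2)

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(0)
        names = [f"t{i}" for i in range(8)]
        src = random_tree(names, rng)
        for clade in src.find_clades():
            if clade.branch_length is not None:
                clade.branch_length = float(rng.uniform(0.1, 1.0))
        D = np.zeros((8, 8))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i < j:
                    D[i, j] = D[j, i] = src.distance(x, y)
        t1 = neighbor_joining(DistanceMatrix(names, D))
        perm = list(rng.permutation(8))
        t2 = neighbor_joining(
            DistanceMatrix([names[i] for i in perm], D[np.ix_(perm, perm)])
        )
        assert rf_distance(t1, t2) == 0


class TestRfDistance:
    def test_identical_trees(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_matches_dendropy_on_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            names = [f"t{i}" for i in range(n)]
            t1, t2 = random_tree(names, rng), random_tree(names, rng)
            mine = rf_distance(t1, t2)
            assert mine == dendropy_rf(t1, t2)
            assert mine == rf_distance(t2, t1) <= rf_max(n)

    def test_too_few_common_leaves(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,B:1):1,(X:1,Y:1):1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestPermutationTest:
    def test_self_comparison_minimal_p(self):
        rng = np.random.default_rng(1)
        t = random_tree([f"t{i}" for i in range(10)], rng)
        res = rf_permutation_test(t, t, n_perm=200, seed=5)
        assert res.observed_rf == 0
        assert res.p_empirical >= 1 / 201
        assert res.p_empirical < 0.05
        assert res.null_mean > 0

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(2)
        names = [f"t{i}" for i in range(12)]
        t1, t2 = random_tree(names, rng), random_tree(names, rng)
        small = rf_permutation_test(t1, t2, n_perm=300, seed=1)
        big = rf_permutation_test(t1, t2, n_perm=3000, seed=2)
        se = small.null_sd / np.sqrt(small.n_perm)
        assert abs(small.null_mean - big.null_mean) < 3 * se + 1e-9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        names = [f"t{i}" for i in range(9)]
        t1, t2 = random_tree(names, rng), random_tree(names, rng)
        r1 = rf_permutation_test(t1, t2, n_perm=100, seed=9)
        r2 = rf_permutation_test(t1, t2, n_perm=100, seed=9)
        assert (r1.null_mean, r1.p_empirical, r1.p_randomized) == (
            r2.null_mean,
            r2.p_empirical,
            r2.p_randomized,
        )


class TestBootstrapAndCollapse:
    # columns 0-7 support the split {a,b}; columns 8-15 support {c,d};
    # no column conflicts with the tree ((a,b),(c,d),e)
    CLEAN = MSA(
        [
            ("a", "AAAAAAAATTTTTTTT"),
            ("b", "AAAAAAAATTTTTTTT"),
            ("c", "CCCCCCCCGGGGGGGG"),
            ("d", "CCCCCCCCGGGGGGGG"),
            ("e", "CCCCCCCCTTTTTTTT"),
        ]
    )

    def test_clean_signal_full_support(self):
        tree = bootstrap_support(self.CLEAN, n_reps=50, seed=1)
        sups = [c.confidence for c in tree.find_clades() if c.confidence is not None]
        assert sups and all(s == 100 for s in sups)

    def test_zero_reps_errors(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.CLEAN, n_reps=0, seed=1)

    def test_same_seed_same_supports(self):
        t1 = bootstrap_support(self.CLEAN, n_reps=30, seed=3)
        t2 = bootstrap_support(self.CLEAN, n_reps=30, seed=3)
        assert write_newick(t1) == write_newick(t2)

    def test_collapse_below_threshold_makes_star(self):
        t = read_newick("((A:1,B:1)49:1,C:1,D:1);")
        out = collapse_low_support(t, threshold=50)
        assert len(out.root.clades) == 4  # polytomy: single weak edge contracted

    def test_support_exactly_at_threshold_retained(self):
        t = read_newick("((A:1,B:1)50:1,C:1,D:1);")
        out = collapse_low_support(t, threshold=50)
        assert len(out.root.clades) == 3

    def test_collapse_preserves_leaves_and_shrinks_splits(self):
        rng = np.random.default_rng(7)
        t = random_tree([f"t{i}" for i in range(10)], rng)
        for c in t.find_clades():
            if c.clades and c is not t.root:
                c.confidence = int(rng.integers(0, 101))
        out = collapse_low_support(t, 60)
        assert sorted(leaf_names(out)) == sorted(leaf_names(t))
        strong = read_newick(write_newick(out))
        assert rf_distance(strong, t) <= rf_max(10)


class TestRooting:
    def test_outgroup_between_cherries(self):
        t = read_newick("((A:1,B:1)90:1,(C:1,D:1)80:1);")
        rooted = root_with_outgroup(t, ["A", "B"])
        kids = {frozenset(l.name for l in c.get_terminals()) for c in rooted.root.clades}
        assert kids == {frozenset("AB"), frozenset("CD")}
        assert rooted.distance("A", "C") == pytest.approx(4.0)

    def test_non_monophyletic_outgroup_errors(self):
        t = read_newick("((A:1,B:1)90:1,(C:1,D:1)80:1);")
        with pytest.raises(ValueError, match="A.*C"):
            root_with_outgroup(t, ["A", "C"])

    def test_single_leaf_outgroup_roots_pendant_edge(self):
        t = read_newick("((A:1,B:1)90:1,(C:1,D:1)80:1);")
        rooted = root_with_outgroup(t, ["A"])
        og = [c for c in rooted.root.clades if not c.clades]
        assert og and og[0].name == "A" and og[0].branch_length == pytest.approx(0.5)
        assert rooted.distance("A", "C") == pytest.approx(4.0)

    def test_rooting_preserves_unrooted_topology(self):
        rng = np.random.default_rng(8)
        t = random_tree([f"t{i}" for i in range(9)], rng)
        rooted = root_with_outgroup(t, ["t0"])
        assert rf_distance(t, rooted) == 0


class TestDelineateClades:
    TREE = "(((q1:1,q2:1)95:1,(q3:1,q4:1)60:1)90:1,(r1:1,q5:1)99:1,out:1);"

    def test_maximal_pure_query_clades(self):
        t = read_newick(self.TREE)
        clades, unassigned = delineate_clades(t, {"q1", "q2", "q3", "q4", "q5"})
        assert clades == {"clade_1": {"q1", "q2", "q3", "q4"}}
        assert unassigned == {"q5"}

    def test_low_support_everywhere_leaves_all_unassigned(self):
        t = read_newick("((q1:1,q2:1)40:1,(q3:1,q4:1)70:1,out:1);")
        clades, unassigned = delineate_clades(t, {"q1", "q2", "q3", "q4"})
        assert clades == {} and unassigned == {"q1", "q2", "q3", "q4"}

    def test_nested_supported_clades_report_only_maximal(self):
        t = read_newick("(((q1:1,q2:1)99:1,q3:1)95:1,(r1:1,r2:1)90:1,out:1);")
        clades, _ = delineate_clades(t, {"q1", "q2", "q3"})
        assert clades == {"clade_1": {"q1", "q2", "q3"}}


class TestNewickIO:
    def test_round_trip_topology_supports_lengths(self):
        text = "((A:1.5,B:0.5)88:2,(C:1,D:1)42:1,E:3);"
        t = read_newick(text)
        back = read_newick(write_newick(t))
        assert rf_distance(t, back) == 0
        sups = sorted(
            c.confidence for c in back.find_clades() if c.confidence is not None
        )
        assert sups == [42, 88]
        assert back.distance("A", "B") == pytest.approx(2.0)
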