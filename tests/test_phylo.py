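import numpy as np
import pytest

import symmeta as sm
from symmeta.phylo import (
    PhyloError,
    bm_correlation,
    expand_populations,
    prune_to,
    read_newick,
    substitute_tips,
    tip_labels,
    write_newick,
)

from _oracles import bm_correlation_bruteforce, pairwise_tip_distances


class TestNewickIO:
    def test_three_tip_parse(self, three_tip_tree):
        assert sorted(tip_labels(three_tip_tree)) == ["A", "B", "C"]
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in three_tip_tree.leaf_node_iter()
        }
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_duplicate_tips_rejected(self):
        with pytest.raises(PhyloError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(PhyloError, match="malformed"):
            read_newick("((A:1,B:1:1,C;")

    def test_missing_length_rejected_unless_imputed(self):
        with pytest.raises(PhyloError, match="branch length"):
            read_newick("((A:1,B),C:2);")
        t = read_newick("((A:1,B),C:2);", missing_length=1.0)
        assert sorted(tip_labels(t)) == ["A", "B", "C"]

    @pytest.mark.parametrize("seed", range(10))
    def test_write_read_roundtrip_preserves_distances(self, seed):
        t = sm.simulate_tree(12, seed)
        t2 = read_newick(write_newick(t))
        d1, lab1 = pairwise_tip_distances(t)
        d2, lab2 = pairwise_tip_distances(t2)
        assert lab1 == lab2
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestSubstituteTips:
    def test_relabel_preserves_everything_else(self, three_tip_tree):
        t = substitute_tips(three_tip_tree, {"D": "C"})
        assert sorted(tip_labels(t)) == ["A", "B", "D"]
        d, labels = pairwise_tip_distances(t)
        assert d[labels.index("A"), labels.index("D")] == pytest.approx(4.0)

    def test_empty_table_is_identity(self, three_tip_tree):
        t = substitute_tips(three_tip_tree, {})
        assert sorted(tip_labels(t)) == ["A", "B", "C"]

    def test_absent_standin_and_clash_rejected(self, three_tip_tree):
        with pytest.raises(PhyloError, match="Z"):
            substitute_tips(three_tip_tree, {"D": "Z"})
        with pytest.raises(PhyloError, match="already present"):
            substitute_tips(three_tip_tree, {"A": "C"})

    def test_untouched_distances_preserved_on_larger_tree(self):
        tree = sm.simulate_tree(30, 3)
        labels = tip_labels(tree)
        table = {f"new_{i}": labels[i] for i in range(10)}
        out = substitute_tips(tree, table)
        keep = labels[10:]
        d_before, lab_b = pairwise_tip_distances(prune_to(tree, keep))
        d_after, lab_a = pairwise_tip_distances(prune_to(out, keep))
        assert lab_b == lab_a
        np.testing.assert_allclose(d_before, d_after, atol=1e-12)


class TestExpandPopulations:
    def test_populations_effectively_coincident(self, three_tip_tree):
        t = expand_populations(three_tip_tree, {"A": ["A_1", "A_2"]}, epsilon=1e-6)
        corr = bm_correlation(t)
        i, j = corr.labels.index("A_1"), corr.labels.index("A_2")
        assert corr.matrix[i, j] >= 1.0 - 1e-5

    def test_singletons_only_relabel(self, three_tip_tree):
        t = expand_populations(three_tip_tree, {"A": ["A_1"], "C": ["C_1"]})
        assert sorted(tip_labels(t)) == ["A_1", "B", "C_1"]
        d, labels = pairwise_tip_distances(t)
        assert d[labels.index("A_1"), labels.index("C_1")] == pytest.approx(4.0)

    def test_restriction_to_one_population_matches_unexpanded(self):
        tree = sm.simulate_tree(12, 5)
        base = bm_correlation(tree)
        mult = {lab: [f"{lab}_1", f"{lab}_2"] for lab in base.labels[:6]}
        expanded = bm_correlation(expand_populations(tree, mult))
        chosen = [f"{lab}_1" if lab in mult else lab for lab in base.labels]
        sub = expanded.restrict(chosen)
        np.testing.assert_allclose(sub.matrix, base.matrix, atol=1e-5)

    def test_label_collision_and_bad_epsilon_rejected(self, three_tip_tree):
        with pytest.raises(PhyloError, match="collide"):
            expand_populations(three_tip_tree, {"A": ["B", "A_2"]})
        with pytest.raises(PhyloError, match="epsilon"):
            expand_populations(three_tip_tree, {"A": ["A_1", "A_2"]}, epsilon=0.1)


class TestPruneTo:
    def test_two_tip_distance_preserved(self, three_tip_tree):
        t = prune_to(three_tip_tree, ["A", "B"])
        assert sorted(tip_labels(t)) == ["A", "B"]
        d, labels = pairwise_tip_distances(t)
        assert d[0, 1] == pytest.approx(2.0)

    def test_prune_to_all_is_identity(self, three_tip_tree):
        t = prune_to(three_tip_tree, ["A", "B", "C"])
        d1, l1 = pairwise_tip_distances(three_tip_tree)
        d2, l2 = pairwise_tip_distances(t)
        assert l1 == l2
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_unknown_label_rejected(self, three_tip_tree):
        with pytest.raises(PhyloError, match="Z"):
            prune_to(three_tip_tree, ["A", "Z"])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_subsets_preserve_distance_submatrix(self, seed):
        tree = sm.simulate_tree(20, seed)
        rng = np.random.default_rng(seed)
        subset = sorted(rng.choice(tip_labels(tree), size=8, replace=False))
        d_full, labels = pairwise_tip_distances(tree)
        idx = [labels.index(s) for s in subset]
        d_sub, sub_labels = pairwise_tip_distances(prune_to(tree, subset))
        assert sub_labels == subset
        np.testing.assert_allclose(d_sub, d_full[np.ix_(idx, idx)], atol=1e-9)


class TestBMCorrelation:
    def test_star_tree_gives_identity(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        np.testing.assert_allclose(bm_correlation(t).matrix, np.eye(4), atol=1e-12)

    def test_three_tip_shared_depths(self, three_tip_tree):
        corr = bm_correlation(three_tip_tree)
        df = corr.to_dataframe()
        assert df.loc["A", "B"] == pytest.approx(0.5)
        assert df.loc["A", "C"] == 0.0
        assert df.loc["B", "C"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_trees(self, seed):
        tree = sm.simulate_tree(30, seed)
        corr = bm_correlation(tree)
        ref, ref_labels = bm_correlation_bruteforce(tree)
        got = corr.restrict(ref_labels).matrix
        np.testing.assert_allclose(got, ref, atol=1e-10)
        assert np.linalg.eigvalsh(got).min() >= -1e-10

    def test_branch_scaling_invariance(self):
        tree = sm.simulate_tree(15, 9)
        base = bm_correlation(tree).matrix
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.3
        np.testing.assert_allclose(bm_correlation(tree).matrix, base, atol=1e-12)

    def test_ultrametric_entries_are_mrca_depth_over_depth(self):
        t = read_newick("((A:1,B:1):2,(C:2.5,D:2.5):0.5);")
        df = bm_correlation(t).to_dataframe()
        assert df.loc["A", "B"] == pytest.approx(2.0 / 3.0)
        assert df.loc["C", "D"] == pytest.approx(0.5 / 3.0)
        assert df.loc["A", "C"] == 0.0

    def test_zero_depth_tip_rejected(self):
        with pytest.raises(PhyloError, match="zero"):
            bm_correlation(read_newick("(A:0,B:1);"))
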