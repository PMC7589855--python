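"""Pearson-distance Ward clustering of variables and extracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import nutriscreen as ns
from nutriscreen.hcluster import (
    DistanceMatrix,
    cut_tree,
    form_latent,
    paper_naming,
    pearson_distance,
    two_way_heatmap,
    ward_linkage,
)

from .conftest import node_leaf_sets
from .oracles import ward_merge_sequence


def random_distance(rng, n):
    """Random correlation-style dissimilarity matrix in [0, 2]."""
    x = rng.standard_normal((max(n + 2, 5), n))
    r = np.corrcoef(x, rowvar=False)
    d = 1 - r
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


class TestPearsonDistance:
    def test_self_distance_zero_and_range(self, zscores):
        dm = pearson_distance(zscores["composition"])
        assert np.allclose(np.diag(dm.d), 0.0)
        assert dm.d.min() >= 0.0 and dm.d.max() <= 2.0 + 1e-12

    def test_anticorrelated_columns_at_two(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        dm = pearson_distance(x)
        assert dm.d[0, 1] == pytest.approx(2.0)

    def test_hand_computed_pair(self):
        x = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [1.0, 2.0, 4.0]})
        # r = 0.98198, hence d = 0.01802
        assert pearson_distance(x).d[0, 1] == pytest.approx(0.01802, abs=5e-6)

    def test_constant_item_rejected(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_distance(x)


class TestWardLinkage:
    def test_identical_columns_merge_first_at_zero(self):
        x = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 1.5],
            "b": [2.0, 4.0, 6.0, 3.0],  # perfectly correlated with a
            "c": [3.0, -1.0, 2.0, 8.0],
        })
        tree = ward_linkage(pearson_distance(x))
        left, right, height, size = tree.merges[0]
        assert {tree.labels[int(left)], tree.labels[int(right)]} == {"a", "b"}
        assert height == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    @pytest.mark.parametrize("dialect", ["d", "d2"])
    def test_matches_stepwise_recomputation_oracle(self, dialect):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(4, 9)
            d = random_distance(rng, n)
            labels = [f"v{i}" for i in range(n)]
            tree = ward_linkage(DistanceMatrix(labels, d), dialect)
            expected = ward_merge_sequence(d, dialect)
            got_sets = node_leaf_sets(tree)
            nn = len(labels)
            for step, (a, b, h) in enumerate(expected):
                assert tree.merges[step, 2] == pytest.approx(h, abs=1e-10)
                exp_union = {labels[i] for i in a | b}
                assert got_sets[step] == frozenset(exp_union)

    def test_d2_dialect_matches_scipy_ward(self):
        rng = np.random.default_rng(7)
        d = random_distance(rng, 10)
        tree = ward_linkage(DistanceMatrix([f"v{i}" for i in range(10)], d), "d2")
        Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
        assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(Z[:, 2]), atol=1e-8)

    def test_heights_monotone_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            d = random_distance(rng, n)
            for dialect in ("d", "d2"):
                tree = ward_linkage(DistanceMatrix([f"v{i}" for i in range(n)], d), dialect)
                h = tree.merges[:, 2]
                assert (np.diff(h) >= -1e-10).all()

    def test_gastric_method_pairs_form_subtrees(self, zscores):
        # the three radical-scavenging assays cluster together, as do the
        # two peptide-quantification methods
        tree = ward_linkage(pearson_distance(zscores["gastric"]))
        sets = node_leaf_sets(tree)
        assert frozenset({"ABTS_G", "FRAP_G", "DPPH_G"}) in sets
        assert frozenset({"DirectDetect_G", "FreeNH2_G"}) in sets


class TestCutTree:
    def test_extreme_cuts(self, zscores):
        tree = ward_linkage(pearson_distance(zscores["gastric"]))
        assert cut_tree(tree, 1) == [sorted(tree.labels, key=tree.labels.index)]
        singles = cut_tree(tree, tree.n_leaves)
        assert sorted(map(tuple, singles)) == sorted([(l,) for l in tree.labels])

    def test_k_out_of_range(self, zscores):
        tree = ward_linkage(pearson_distance(zscores["gastric"]))
        for k in (0, 8):
            with pytest.raises(ValueError):
                cut_tree(tree, k)

    def test_cuts_are_nested(self, zscores):
        tree = ward_linkage(pearson_distance(zscores["composition"]))
        prev = cut_tree(tree, 1)
        for k in range(2, tree.n_leaves + 1):
            cur = cut_tree(tree, k)
            prev_sets = [set(c) for c in prev]
            for cluster in cur:
                assert any(set(cluster) <= p for p in prev_sets)
            prev = cur

    def test_composition_cut_contains_branched_amino_acid_block(self, zscores):
        tree = ward_linkage(pearson_distance(zscores["composition"]))
        clusters = [frozenset(c) for c in cut_tree(tree, 9)]
        assert frozenset({"Thr", "Ile", "Val", "Leu", "Lys"}) in clusters

    def test_all_published_member_sets_recovered_at_default_cuts(
        self, zscores, expected_latents
    ):
        for vs, k in (("composition", 9), ("gastric", 3), ("intestinal", 3)):
            tree = ward_linkage(pearson_distance(zscores[vs]))
            got = {frozenset(c) for c in cut_tree(tree, k)}
            expected = {frozenset(lv.members) for lv in expected_latents if lv.var_set == vs}
            assert got == expected


class TestFormLatent:
    def test_published_names_applied(self, zscores, expected_latents):
        tree = ward_linkage(pearson_distance(zscores["composition"]))
        latents = form_latent(cut_tree(tree, 9), "composition", paper_naming(expected_latents))
        names = {lv.name for lv in latents}
        assert "C and W" in names and "TIVLK" in names
        cw = next(lv for lv in latents if lv.name == "C and W")
        assert set(cw.members) == {"Cys", "Trp"}

    def test_auto_name_and_singletons(self):
        latents = form_latent([["Alpha", "Beta"], ["Gamma"]], "composition")
        assert [lv.name for lv in latents] == ["AB", "G"]
        assert latents[1].members == ["Gamma"]

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            form_latent([["a", "b"], ["b"]], "composition")


class TestTwoWayHeatmap:
    def test_layout_is_permutation(self, zscores):
        z = zscores["gastric"]
        layout = two_way_heatmap(z)
        assert sorted(layout.row_order) == sorted(z.index)
        assert sorted(layout.col_order) == sorted(z.columns)
        assert np.allclose(np.sort(layout.matrix.values.ravel()),
                           np.sort(z.values.ravel()))

    def test_row_tree_is_extract_clustering(self, zscores):
        z = zscores["gastric"]
        layout = two_way_heatmap(z)
        direct = ward_linkage(pearson_distance(z, "extracts"))
        assert np.allclose(layout.row_tree.merges, direct.merges)
        assert layout.row_tree.labels == direct.labels

    def test_carbohydrate_rich_extracts_share_a_small_subtree(self, zscores):
        # cheese powder and the fava beans are the sugar/carb-heavy extracts;
        # their smallest common subtree adds only the lactose-rich casein
        # concentrate D3
        layout = two_way_heatmap(zscores["composition"])
        sets = node_leaf_sets(layout.row_tree)
        target = {"D1", "P1", "P2"}
        smallest = min((s for s in sets if target <= s), key=len)
        assert smallest <= {"D1", "D3", "P1", "P2"}
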