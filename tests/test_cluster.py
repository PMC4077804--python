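import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from spindex.cluster import (
    average_linkage,
    centered_correlation,
    cluster_matrix,
    preprocess,
    similarity_matrix,
    write_cdt,
)


def brute_force_average_linkage(dist: np.ndarray):
    """O(n^3) re-scan oracle: at each step recompute every inter-cluster
    mean leaf-pair distance from the original matrix."""
    clusters = [{i} for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


class TestPreprocess:
    def test_constant_row_centres_to_zero(self):
        mat = pd.DataFrame({"s1": [4.0], "s2": [4.0], "s3": [4.0]}, index=["g"])
        out = preprocess(mat, ["g"])
        assert (out.loc["g"] == 0).all()

    def test_log2_then_median_centre(self):
        mat = pd.DataFrame([[1.0, 2.0, 4.0]], index=["g"], columns=list("abc"))
        out = preprocess(mat, ["g"])
        np.testing.assert_allclose(out.loc["g"], [-1.0, 0.0, 1.0])

    def test_single_pass_contract(self):
        mat = pd.DataFrame([[1.0, 2.0, 4.0]], index=["g"], columns=list("abc"))
        out = preprocess(mat, ["g"])
        with pytest.raises(ValueError, match="already"):
            preprocess(out, ["g"])

    def test_non_positive_value_names_gene(self):
        mat = pd.DataFrame([[1.0, 0.0, 4.0]], index=["bad_gene"], columns=list("abc"))
        with pytest.raises(ValueError, match="bad_gene"):
            preprocess(mat, ["bad_gene"])


class TestCenteredCorrelation:
    def test_self_similarity(self):
        assert centered_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anti_correlation(self):
        assert centered_correlation([1, 2, 3], [5, 4, 3]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # r = 3 / (sqrt(2) * sqrt(42)/3) = 9/sqrt(84)
        got = centered_correlation([1, 2, 3], [1, 2, 4])
        assert got == pytest.approx(9 / np.sqrt(84))
        assert got == pytest.approx(np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1])

    def test_zero_variance_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert centered_correlation([2, 2, 2], [1, 2, 3]) == 0.0

    def test_matrix_form_matches_pairwise(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(6, 5))
        sim = similarity_matrix(rows)
        for i in range(6):
            for j in range(6):
                assert sim[i, j] == pytest.approx(
                    centered_correlation(rows[i], rows[j]), abs=1e-12
                )


class TestAverageLinkage:
    def test_identical_rows_merge_first_at_zero(self):
        d = np.array(
            [[0, 0, 2.0], [0, 0, 2.0], [2.0, 2.0, 0]]
        )
        tree = average_linkage(d)
        assert (tree.merges[0].left, tree.merges[0].right) == (0, 1)
        assert tree.merges[0].distance == 0.0

    def test_three_leaf_hand_trace(self):
        # d(0,1)=1, d(0,2)=4, d(1,2)=5 -> merge (0,1) at 1, then at (4+5)/2
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = average_linkage(d)
        assert [m.distance for m in tree.merges] == [1.0, 4.5]
        assert (tree.merges[0].left, tree.merges[0].right) == (0, 1)
        assert tree.leaf_order() == [0, 1, 2]

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            average_linkage(np.array([[0, 1], [2, 0]], dtype=float))

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = average_linkage(d)
        got = [m.distance for m in tree.merges]
        np.testing.assert_allclose(got, brute_force_average_linkage(d), rtol=1e-10)
        ref = linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(sorted(got), sorted(ref[:, 2]), rtol=1e-10)

    def test_merge_heights_non_decreasing_on_metric_input(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        heights = [m.distance for m in average_linkage(d).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestClusterMatrix:
    @pytest.fixture
    def prepped(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(
            rng.uniform(1, 16, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        return preprocess(mat, mat.index)

    def test_orders_are_permutations_and_trees_complete(self, prepped):
        res = cluster_matrix(prepped)
        assert sorted(res.gene_order) == list(range(10))
        assert sorted(res.sample_order) == list(range(6))
        assert len(res.gene_tree.merges) == 9
        assert len(res.sample_tree.merges) == 5

    def test_invariant_to_row_order(self, prepped):
        res = cluster_matrix(prepped)
        shuffled = prepped.iloc[::-1]
        res2 = cluster_matrix(shuffled)
        np.testing.assert_allclose(
            sorted(m.distance for m in res.gene_tree.merges),
            sorted(m.distance for m in res2.gene_tree.merges),
            rtol=1e-10,
        )
        assert set(map(frozenset, _flat_clusters(res))) == set(
            map(frozenset, _flat_clusters(res2))
        )

    def test_treeview_files_written(self, prepped, tmp_path):
        res = cluster_matrix(prepped)
        paths = write_cdt(res, tmp_path / "out")
        cdt = (tmp_path / "out.cdt").read_text().splitlines()
        assert cdt[0].startswith("GID\tNAME\tGWEIGHT")
        assert len(cdt) == 3 + 10  # header rows + one line per gene
        gtr = (tmp_path / "out.gtr").read_text().splitlines()
        assert len(gtr) == 9
        assert gtr[0].startswith("NODE1X\t")
        atr = (tmp_path / "out.atr").read_text().splitlines()
        assert len(atr) == 5


def _flat_clusters(res):
    """Leaf-name sets of every internal node of the gene tree."""
    names = list(res.matrix.index)
    sets = {i: {names[i]} for i in range(len(names))}
    out = []
    for m in res.gene_tree.merges:
        sets[m.node] = sets[m.left] | sets[m.right]
        out.append(sets[m.node])
    return out
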