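import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from plankgrid.assemblage import (
    _fanny_objective,
    fanny_cluster,
    hellinger_distance,
    hellinger_transform,
    kgs_penalty,
    mantel_correlation,
    max_membership_map,
    select_k_table,
    silhouette,
    split_dominant_secondary,
)


def two_block_distances(gap=10.0, within=0.1, n=5):
    D = np.full((2 * n, 2 * n), gap)
    D[:n, :n] = within
    D[n:, n:] = within
    np.fill_diagonal(D, 0.0)
    return D


class TestSplitDominantSecondary:
    def _matrix(self, totals):
        return pd.DataFrame({t: [v] for t, v in totals.items()})

    def test_one_percent_taxon_is_dominant(self):
        dom, sec, clus = split_dominant_secondary(self._matrix({"a": 99.0, "b": 1.0}))
        assert dom == ["a", "b"] and sec == []

    def test_taxon_at_0_4_percent_is_secondary(self):
        dom, sec, _ = split_dominant_secondary(self._matrix({"a": 99.6, "b": 0.4}))
        assert sec == ["b"]

    def test_excluded_aggregate_left_out_of_clustering_only(self):
        dom, sec, clus = split_dominant_secondary(
            self._matrix({"Copepoda": 10.0, "a": 90.0}), exclusion={"Copepoda"}
        )
        assert "Copepoda" in dom and "Copepoda" not in clus

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            split_dominant_secondary(self._matrix({"a": 0.0}))


class TestHellinger:
    def test_closed_form_rows(self):
        X = pd.DataFrame([[4.0, 0.0, 0.0], [1.0, 1.0, 1.0]], columns=list("abc"))
        Y = hellinger_transform(X)
        assert np.allclose(Y.iloc[0], [1.0, 0.0, 0.0])
        assert np.allclose(Y.iloc[1], np.sqrt(1 / 3))
        X2 = pd.DataFrame([[1.0, 3.0]])
        assert np.allclose(hellinger_transform(X2).iloc[0], [0.5, np.sqrt(3) / 2])

    def test_quarters_row(self):
        Y = hellinger_transform(np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert np.allclose(Y, 0.5)

    def test_zero_row_stays_zero(self):
        Y = hellinger_transform(np.array([[0.0, 0.0]]))
        assert np.all(Y == 0.0)

    def test_unit_norm_and_distance_bound(self, rng):
        X = rng.lognormal(0, 1, size=(20, 6))
        Y = hellinger_transform(X)
        assert np.allclose(np.linalg.norm(Y, axis=1), 1.0)
        D = hellinger_distance(Y)
        assert D.max() <= np.sqrt(2) + 1e-12
        assert np.allclose(np.diag(D), 0.0)

    def test_disjoint_rows_reach_sqrt2(self):
        Y = hellinger_transform(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert hellinger_distance(Y)[0, 1] == pytest.approx(np.sqrt(2))

    def test_distance_matches_elementwise_oracle(self, rng):
        X = rng.lognormal(0, 1, size=(4, 3))
        Y = np.sqrt(X / X.sum(axis=1, keepdims=True))
        D = hellinger_distance(hellinger_transform(X))
        for i in range(4):
            for j in range(4):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((Y[i] - Y[j]) ** 2).sum()), abs=1e-12
                )


class TestFanny:
    def test_zero_distances_give_zero_objective(self):
        D = np.zeros((6, 6))
        m = fanny_cluster(D, 2, 1.2, seed=0)
        assert m.objective == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(m.U.sum(axis=1), 1.0)

    def test_two_blocks_recovered_with_high_membership(self):
        m = fanny_cluster(two_block_distances(), 2, 1.2, seed=0)
        top = m.U.max(axis=1)
        labels, _ = max_membership_map(m.U)
        assert np.all(top > 0.9)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k1_relaxation_objective_formula(self, rng):
        D = squareform(pdist(rng.normal(size=(8, 2))))
        U = np.ones((8, 1))
        assert _fanny_objective(U, D, 1.2) == pytest.approx(D.sum() / 16.0)

    def test_row_sums_and_range(self, rng):
        D = squareform(pdist(rng.normal(size=(20, 3))))
        m = fanny_cluster(D, 4, 1.2, seed=1)
        assert np.allclose(m.U.sum(axis=1), 1.0, atol=1e-9)
        assert m.U.min() >= 0.0 and m.U.max() <= 1.0

    def test_scaling_distances_scales_objective_only(self, rng):
        D = squareform(pdist(rng.normal(size=(12, 2))))
        a = fanny_cluster(D, 3, 1.2, seed=5)
        b = fanny_cluster(4.0 * D, 3, 1.2, seed=5)
        assert b.objective == pytest.approx(4.0 * a.objective, rel=1e-6)
        assert np.allclose(a.U, b.U, atol=1e-6)

    def test_matches_reference_fanny_solution(self):
        """Two tight planar blocks: objective and memberships agree with the
        classical dissimilarity-based fuzzy clustering solution computed
        independently with cluster::fanny (memb.exp 1.2), frozen here."""
        pts = np.array(
            [
                [0.068547922357, -0.005306225805],
                [-0.028234908570, 0.075576099872],
                [0.018156420567, -0.004732951921],
                [0.031643130248, 0.100921185694],
                [0.020213416157, -0.003135704953],
                [3.065243482711, 3.031797519904],
                [3.114332269635, 2.985787353929],
                [2.930556964944, 2.867177228955],
                [2.986060561659, 2.877976653571],
                [2.993333933180, 3.066005667287],
            ]
        )
        D = squareform(pdist(pts))
        m = fanny_cluster(D, 2, 1.2, seed=0, tol=1e-12)
        assert m.objective == pytest.approx(0.4637302721, abs=1e-8)
        assert np.all(m.U.max(axis=1) > 1 - 1e-6)

    def test_row_permutation_equivariance(self, rng):
        D = squareform(pdist(rng.normal(size=(10, 2))))
        ids = [f"c{i}" for i in range(10)]
        perm = rng.permutation(10)
        a = fanny_cluster(D, 3, 1.2, seed=2, cell_ids=ids)
        b = fanny_cluster(
            D[np.ix_(perm, perm)], 3, 1.2, seed=2, cell_ids=[ids[i] for i in perm]
        )
        assert np.allclose(a.U[perm], b.U, atol=1e-6)

    def test_invalid_k_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            fanny_cluster(D, 4, 1.2)


class TestMaxMembership:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.7, 0.3), (1, 0.7)),
            ((0.5, 0.5), (1, 0.5)),
            ((0.2, 0.2, 0.2, 0.2, 0.2), (1, 0.2)),
        ],
    )
    def test_labels_and_ties(self, row, expected):
        labels, vals = max_membership_map(np.array([row]))
        assert (labels[0], vals[0]) == pytest.approx(expected)


class TestSilhouette:
    def test_perfectly_separated_pairs(self):
        D = two_block_distances(gap=10.0, within=0.0, n=2)
        s, mean = silhouette(D, np.array([1, 1, 2, 2]))
        assert np.allclose(s, 1.0) and mean == 1.0

    def test_singleton_scores_zero(self):
        D = two_block_distances(gap=5.0, within=0.5, n=2)
        s, _ = silhouette(D[:3, :3], np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_five_point_hand_example(self):
        """Line points 0,1 | 10,11,12: widths from the direct formula."""
        pts = np.array([0.0, 1.0, 10.0, 11.0, 12.0])
        D = np.abs(pts[:, None] - pts[None, :])
        s, mean = silhouette(D, np.array([1, 1, 2, 2, 2]))
        expected = [0.9090909091, 0.9, 0.8421052632, 0.9047619048, 0.8695652174]
        assert np.allclose(s, expected)
        assert mean == pytest.approx(0.8851046589)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 3)), np.array([1, 1, 1]))


class TestMantel:
    def test_perfect_binary_alignment(self):
        D = two_block_distances(gap=3.0, within=1.0, n=3)
        assert mantel_correlation(D, np.array([1] * 3 + [2] * 3)) == pytest.approx(1.0)

    def test_constant_distances_undefined(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            mantel_correlation(D, np.array([1, 1, 2, 2]))

    def test_six_point_worked_example(self):
        """Random symmetric D with labels (1,1,1,2,2,2): value frozen from
        the direct Pearson formula on the lower triangles."""
        rng = np.random.default_rng(7)
        D = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        D[iu] = rng.uniform(1, 5, 15)
        D += D.T
        r = mantel_correlation(D, np.array([1, 1, 1, 2, 2, 2]))
        assert r == pytest.approx(-0.2877509268, abs=1e-9)


class TestKgsPenalty:
    def test_two_tight_blocks_minimized_at_two(self):
        D = two_block_distances(gap=10.0, within=0.1, n=5)
        pen = kgs_penalty(D, range(2, 7))
        assert pen.idxmin() == 2

    def test_equal_distances_flat_spread(self):
        D = np.ones((6, 6)) - np.eye(6)
        pen = kgs_penalty(D, range(2, 5))
        assert np.allclose(pen.values, 1.0 + np.array([2, 3, 4]))
        assert pen.idxmin() == 2

    def test_single_k_rescales_to_one(self):
        D = two_block_distances()
        pen = kgs_penalty(D, [3])
        assert pen.loc[3] == pytest.approx(1.0 + 3.0)


class TestSelectKTable:
    def test_single_k_gives_one_row(self):
        D = two_block_distances()
        out = select_k_table(D, [2], seed=0)
        assert list(out.table.index) == [2]
        assert out.table.loc[2, "mean_silhouette"] > 0.9

    def test_duplicate_cells_do_not_change_argmax(self, rng):
        base = rng.normal(size=(12, 2))
        base[:6] += 8.0
        D1 = squareform(pdist(base))
        dup = np.vstack([base, base[:3]])
        D2 = squareform(pdist(dup))
        ids1 = [f"c{i}" for i in range(12)]
        ids2 = ids1 + [f"d{i}" for i in range(3)]
        t1 = select_k_table(D1, range(2, 5), seed=0, cell_ids=ids1).table
        t2 = select_k_table(D2, range(2, 5), seed=0, cell_ids=ids2).table
        assert t1["mean_silhouette"].idxmax() == t2["mean_silhouette"].idxmax() == 2
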