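import numpy as np
import pytest

from sciber import (
    ExpressionMatrix,
    centroid_pair_matrices,
    cluster_batch,
    project_batch,
)
from sciber.matching import MatchedPair


def _pair(q, r, putative=True):
    return MatchedPair("q", q, r, overlap=5, table=(5, 5, 5, 85),
                       p_value=0.01, putative=putative)


def _matrix(values, batch_id="q"):
    values = np.asarray(values, float)
    p, n = values.shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(p)],
                            [f"c{j}" for j in range(n)], batch_id)


class TestCentroidPairMatrices:
    def _assignments(self, rng):
        Xq = _matrix(np.abs(rng.normal(2, 1, size=(8, 30))), "q")
        Xr = _matrix(np.abs(rng.normal(2, 1, size=(8, 24))), "r")
        return (cluster_batch(Xq, 3, seed=0), cluster_batch(Xr, 3, seed=1),
                Xq, Xr)

    def test_single_pair_single_columns(self, rng):
        qa, ra, *_ = self._assignments(rng)
        Xc_q, Xc_r = centroid_pair_matrices(qa, ra, [_pair(1, 2)])
        np.testing.assert_allclose(Xc_q[:, 0], qa.centroid_of(1))
        np.testing.assert_allclose(Xc_r[:, 0], ra.centroid_of(2))

    def test_column_order_follows_pair_order(self, rng):
        qa, ra, *_ = self._assignments(rng)
        pairs = [_pair(1, 1), _pair(2, 3), _pair(3, 2)]
        Xc_q, Xc_r = centroid_pair_matrices(qa, ra, pairs)
        Xc_q2, Xc_r2 = centroid_pair_matrices(qa, ra, pairs[::-1])
        np.testing.assert_allclose(Xc_q, Xc_q2[:, ::-1])
        np.testing.assert_allclose(Xc_r, Xc_r2[:, ::-1])

    def test_repeated_reference_cluster_duplicates_column(self, rng):
        qa, ra, *_ = self._assignments(rng)
        Xc_q, Xc_r = centroid_pair_matrices(qa, ra, [_pair(1, 2), _pair(2, 2)])
        np.testing.assert_allclose(Xc_r[:, 0], Xc_r[:, 1])

    def test_centroids_match_brute_force_means(self, rng):
        qa, ra, Xq, _ = self._assignments(rng)
        pairs = [_pair(k, k) for k in range(1, qa.K + 1)]
        Xc_q, _ = centroid_pair_matrices(qa, ra, pairs)
        for j, pr in enumerate(pairs):
            members = Xq.values[:, qa.labels == pr.query_cluster]
            np.testing.assert_allclose(Xc_q[:, j], members.mean(axis=1),
                                       atol=1e-8)

    def test_only_putative_pairs_used(self, rng):
        qa, ra, *_ = self._assignments(rng)
        pairs = [_pair(1, 1), _pair(2, 2, putative=False)]
        Xc_q, _ = centroid_pair_matrices(qa, ra, pairs)
        assert Xc_q.shape[1] == 1

    def test_zero_putative_rejected(self, rng):
        qa, ra, *_ = self._assignments(rng)
        with pytest.raises(ValueError, match="omega"):
            centroid_pair_matrices(qa, ra, [_pair(1, 1, putative=False)])


class TestProjectBatch:
    def test_query_centroid_maps_to_reference_centroid(self, rng):
        p, m = 20, 4
        Xc_q = rng.normal(1.0, 1.0, size=(p, m))
        Xc_r = rng.normal(2.0, 1.0, size=(p, m))
        X = _matrix(np.abs(np.column_stack([Xc_q[:, 2]] * 3)))
        out = project_batch(X, np.abs(Xc_q), np.abs(Xc_r))
        np.testing.assert_allclose(out.values[:, 0], np.abs(Xc_r)[:, 2],
                                   atol=1e-8)

    def test_identity_on_own_span_with_orthonormal_columns(self):
        # non-negative orthonormal basis: disjoint normalized blocks
        Q = np.zeros((15, 3))
        for j in range(3):
            Q[5 * j: 5 * (j + 1), j] = 1.0 / np.sqrt(5)
        coeffs = np.abs(np.random.default_rng(4).normal(size=(3, 6)))
        X = _matrix(Q @ coeffs)
        out = project_batch(X, Q, Q)
        np.testing.assert_allclose(out.values, X.values, atol=1e-8)

    def test_matches_normal_equation_oracle(self, rng):
        p, m, n = 30, 4, 12
        Xc_q = rng.normal(1, 1, size=(p, m))
        Xc_r = rng.normal(1, 1, size=(p, m))
        X = _matrix(np.abs(rng.normal(2, 1, size=(p, n))))
        out = project_batch(X, Xc_q, Xc_r)
        for j in range(n):
            beta = np.linalg.solve(Xc_q.T @ Xc_q, Xc_q.T @ X.values[:, j])
            np.testing.assert_allclose(out.values[:, j], Xc_r @ beta,
                                       rtol=1e-8, atol=1e-8)

    def test_linearity_interpolation(self, rng):
        p, m = 25, 3
        Xc_q = rng.normal(1, 1, size=(p, m))
        Xc_r = rng.normal(1, 1, size=(p, m))
        x, y = np.abs(rng.normal(2, 1, size=(p, 2))).T
        for alpha in (0.0, 0.25, 0.5, 1.0):
            mix = _matrix((alpha * x + (1 - alpha) * y)[:, None])
            out_mix = project_batch(mix, Xc_q, Xc_r).values[:, 0]
            out_x = project_batch(_matrix(x[:, None]), Xc_q, Xc_r).values[:, 0]
            out_y = project_batch(_matrix(y[:, None]), Xc_q, Xc_r).values[:, 0]
            np.testing.assert_allclose(out_mix,
                                       alpha * out_x + (1 - alpha) * out_y,
                                       atol=1e-8)

    def test_midpoint_of_centroids_maps_to_midpoint(self, rng):
        p, m = 20, 4
        Xc_q = np.abs(rng.normal(2, 1, size=(p, m)))
        Xc_r = np.abs(rng.normal(2, 1, size=(p, m)))
        mid = 0.5 * (Xc_q[:, 0] + Xc_q[:, 1])
        out = project_batch(_matrix(mid[:, None]), Xc_q, Xc_r)
        np.testing.assert_allclose(out.values[:, 0],
                                   0.5 * (Xc_r[:, 0] + Xc_r[:, 1]), atol=1e-8)

    def test_rank_deficient_uses_min_norm_solution(self, rng):
        p = 10
        col = np.abs(rng.normal(2, 1, size=p))
        Xc_q = np.column_stack([col, col])  # duplicated centroid
        Xc_r = np.abs(rng.normal(2, 1, size=(p, 2)))
        X = _matrix(col[:, None])
        out = project_batch(X, Xc_q, Xc_r)
        assert np.all(np.isfinite(out.values))
        # min-norm beta splits the coordinate equally over the twin columns
        np.testing.assert_allclose(out.values[:, 0],
                                   0.5 * (Xc_r[:, 0] + Xc_r[:, 1]), atol=1e-8)

    def test_output_preserves_ids_and_shape(self, rng):
        X = _matrix(np.abs(rng.normal(2, 1, size=(12, 7))))
        Xc = np.abs(rng.normal(2, 1, size=(12, 3)))
        out = project_batch(X, Xc, Xc)
        assert out.gene_ids == X.gene_ids
        assert out.cell_ids == X.cell_ids
        assert out.values.shape == X.values.shape

    def test_clamp_nonnegative(self, rng):
        X = _matrix(np.abs(rng.normal(1, 1, size=(8, 5))))
        Xc_q = np.abs(rng.normal(1, 1, size=(8, 2)))
        Xc_r = -np.ones((8, 2))  # forces negative output
        out = project_batch(X, Xc_q, Xc_r, clamp_nonnegative=True)
        assert np.all(out.values >= 0)

    def test_dimension_mismatch_and_zero_basis_rejected(self, rng):
        X = _matrix(np.abs(rng.normal(1, 1, size=(8, 5))))
        with pytest.raises(ValueError):
            project_batch(X, np.ones((7, 2)), np.ones((8, 2)))
        with pytest.raises(ValueError):
            project_batch(X, np.zeros((8, 2)), np.ones((8, 2)))
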