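import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import random_symmetric_similarity
from wgrmf.factorization import (
    WGRMF,
    svd_initialize,
    update_lncrna_factors,
    update_protein_factors,
    wgrmf_objective,
)
from wgrmf.graph import normalized_laplacian


def objective_oracle(Y, A, B, W, L_l, L_p, lf, ll, lp):
    """Naive scalar-loop evaluation of the weighted objective."""
    n, m = Y.shape
    k = A.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(m):
            r = Y[i, j] - sum(A[i, t] * B[j, t] for t in range(k))
            total += W[i, j] * r * r
    total += lf * ((A**2).sum() + (B**2).sum())
    total += ll * np.trace(A.T @ L_l @ A)
    total += lp * np.trace(B.T @ L_p @ B)
    return total


def small_problem(rng, n=6, m=4, k=2):
    Y = (rng.random((n, m)) < 0.4).astype(float)
    Y[0, 0] = 1.0  # keep at least one positive
    W = np.where(Y == 1, 1.0, 0.1)
    L_l = normalized_laplacian(random_symmetric_similarity(rng, n))[1]
    L_p = normalized_laplacian(random_symmetric_similarity(rng, m))[1]
    A = rng.standard_normal((n, k))
    B = rng.standard_normal((m, k))
    return Y, W, L_l, L_p, A, B


class TestSvdInitialize:
    def test_exact_rank_one(self):
        Y = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
        A, B = svd_initialize(Y, 1)
        assert np.linalg.norm(Y - A @ B.T) < 1e-10

    def test_full_rank_reconstruction(self, rng):
        Y = rng.random((5, 4))
        A, B = svd_initialize(Y, 4)
        assert np.linalg.norm(Y - A @ B.T) < 1e-8

    def test_residual_matches_trailing_singular_values(self, rng):
        """Truncated residual equals sqrt(sum of trailing sigma^2), with the
        singular values taken from an independent eigendecomposition."""
        Y = rng.standard_normal((8, 5))
        A, B = svd_initialize(Y, 3)
        eigvals = np.sort(np.linalg.eigvalsh(Y.T @ Y))[::-1]
        expected = np.sqrt(max(eigvals[3:].sum(), 0.0))
        assert np.linalg.norm(Y - A @ B.T) == pytest.approx(expected, abs=1e-8)

    def test_rank_domain(self):
        with pytest.raises(ValueError):
            svd_initialize(np.ones((3, 2)), 3)


class TestObjective:
    def test_zero_factors_counts_positives(self):
        Y = np.array([[1.0, 0.0], [1.0, 1.0]])
        A, B = np.zeros((2, 1)), np.zeros((2, 1))
        Z = np.zeros((2, 2))
        val = wgrmf_objective(Y, A, B, np.ones_like(Y), Z, Z, 0, 0, 0)
        assert val == Y.sum()  # binary Y: sum of squares = number of ones

    def test_exact_factorization_is_zero(self, rng):
        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((3, 2))
        Y = A @ B.T
        Z4, Z3 = np.zeros((4, 4)), np.zeros((3, 3))
        assert wgrmf_objective(Y, A, B, np.ones_like(Y), Z4, Z3, 0, 0, 0) < 1e-20

    def test_matches_scalar_loop_oracle(self, rng):
        Y, W, L_l, L_p, A, B = small_problem(rng)
        got = wgrmf_objective(Y, A, B, W, L_l, L_p, 0.5, 0.3, 0.2)
        want = objective_oracle(Y, A, B, W, L_l, L_p, 0.5, 0.3, 0.2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_nonfinite_factors_rejected(self):
        Y = np.ones((2, 2))
        A = np.array([[np.nan], [0.0]])
        with pytest.raises(ValueError):
            wgrmf_objective(Y, A, np.zeros((2, 1)), Y, np.zeros((2, 2)),
                            np.zeros((2, 2)), 0, 0, 0)


class TestRowUpdates:
    def test_orthonormal_projection_closed_form(self, rng):
        Y = rng.random((5, 3))
        B, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        A = rng.standard_normal((5, 3))
        out = update_lncrna_factors(Y, A, B, np.ones_like(Y), np.zeros((5, 5)), 0.0, 0.0)
        np.testing.assert_allclose(out, Y @ B, atol=1e-10)

    def test_zero_basis_shrinks_to_zero(self, rng):
        Y = rng.random((4, 3))
        A = rng.standard_normal((4, 2))
        B = np.zeros((3, 2))
        out = update_lncrna_factors(Y, A, B, np.ones_like(Y), np.zeros((4, 4)), 0.5, 0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_rows_match_convex_minimizer_oracle(self, rng):
        """Without graph coupling each updated row is the exact minimizer of
        the objective in that row with everything else fixed (a generic
        numerical optimizer agrees)."""
        Y, W, _, _, A, B = small_problem(rng, n=4, m=3, k=2)
        lf = 0.4
        out = update_lncrna_factors(Y, A, B, W, np.zeros((4, 4)), lf, 0.0)
        for i in range(4):
            def row_obj(a_i, i=i):
                r = Y[i] - a_i @ B.T
                return W[i] @ (r * r) + lf * a_i @ a_i
            res = minimize(row_obj, A[i], method="BFGS", options={"gtol": 1e-12})
            np.testing.assert_allclose(out[i], res.x, atol=1e-6)

    def test_protein_update_mirrors_lncrna_update(self, rng):
        """On a symmetric problem (square Y, shared Laplacian, A = B) the two
        updates produce identical factors."""
        n = 5
        S = random_symmetric_similarity(rng, n)
        L = normalized_laplacian(S)[1]
        Y = (rng.random((n, n)) < 0.5).astype(float)
        Y = np.maximum(Y, Y.T)
        W = np.where(Y == 1, 1.0, 0.1)
        F = rng.standard_normal((n, 2))
        out_a = update_lncrna_factors(Y, F, F, W, L, 0.5, 0.2)
        out_b = update_protein_factors(Y, F, F, W, L, 0.5, 0.2)
        np.testing.assert_allclose(out_a, out_b, atol=1e-10)


class TestFit:
    def test_reduces_to_low_rank_approximation(self, rng):
        A0 = rng.standard_normal((6, 2))
        B0 = rng.standard_normal((4, 2))
        Y = A0 @ B0.T
        model = WGRMF(n_components=2, lambda_f=0.0, lambda_l=0.0, lambda_p=0.0,
                      unknown_weight=1.0, tol=1e-12)
        model.fit(Y)
        assert model.objective_trace_[-1] < 1e-8

    def test_objective_trace_non_increasing(self, rng):
        Y = (rng.random((10, 8)) < 0.3).astype(float)
        Y[0, 0] = 1.0
        S_l = random_symmetric_similarity(rng, 10)
        S_p = random_symmetric_similarity(rng, 8)
        model = WGRMF(n_components=4).fit(Y, lncrna_sim=S_l, protein_sim=S_p)
        trace = np.array(model.objective_trace_)
        assert (np.diff(trace) <= 1e-8).all()

    def test_normal_equation_residual_at_convergence(self, rng):
        Y, W, L_l, L_p, _, _ = small_problem(rng)
        model = WGRMF(n_components=2, lambda_f=0.5, lambda_l=0.3, lambda_p=0.2,
                      unknown_weight=0.1, tol=1e-14, max_sweeps=5000)
        model.fit(Y, lncrna_sim=None, protein_sim=None, W=W)
        A, B = model.A_, model.B_
        for i in range(Y.shape[0]):
            M = B.T @ np.diag(W[i]) @ B + 0.5 * np.eye(2)
            resid = A[i] @ M - (W[i] * Y[i]) @ B
            assert np.linalg.norm(resid) < 1e-6

    def test_graph_regularization_pulls_neighbors_together(self, rng):
        """With a two-block similarity graph, within-block latent distances
        shrink relative to between-block ones as lambda_l grows."""
        n, m = 12, 8
        Y = (rng.random((n, m)) < 0.3).astype(float)
        Y[0, 0] = 1.0
        S = np.zeros((n, n))
        S[:6, :6] = 0.9
        S[6:, 6:] = 0.9
        np.fill_diagonal(S, 0.0)

        def ratio(lambda_l):
            model = WGRMF(
                n_components=3, lambda_l=lambda_l, graph_update="exact"
            ).fit(Y, lncrna_sim=S)
            A = model.A_
            within, between = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    d = np.linalg.norm(A[i] - A[j])
                    (within if (i < 6) == (j < 6) else between).append(d)
            return np.mean(within) / np.mean(between)

        assert ratio(5.0) < ratio(0.0)

    def test_rank_capped_at_matrix_size(self, rng):
        Y = (rng.random((5, 3)) < 0.5).astype(float)
        Y[0, 0] = 1.0
        model = WGRMF(n_components=50).fit(Y)
        assert model.rank_ == 3 and model.A_.shape == (5, 3)

    def test_predict_matches_product_oracle(self, rng):
        Y = (rng.random((6, 4)) < 0.4).astype(float)
        Y[0, 0] = 1.0
        model = WGRMF(n_components=2).fit(Y)
        scores = model.predict()
        for i in range(6):
            for j in range(4):
                assert scores[i, j] == pytest.approx(
                    sum(model.A_[i, t] * model.B_[j, t] for t in range(2)), abs=1e-10
                )

    def test_predict_requires_fit(self):
        with pytest.raises(AttributeError):
            WGRMF().predict()

    def test_zero_factors_give_zero_scores(self):
        model = WGRMF()
        model.A_ = np.zeros((3, 2))
        model.B_ = np.zeros((2, 2))
        np.testing.assert_array_equal(model.predict(), np.zeros((3, 2)))

    def test_exact_and_jacobi_agree_at_convergence(self, rng):
        Y, W, L_l, L_p, _, _ = small_problem(rng)
        S_l = random_symmetric_similarity(rng, 6)
        S_p = random_symmetric_similarity(rng, 4)
        kw = dict(n_components=2, tol=1e-13, max_sweeps=5000)
        m1 = WGRMF(graph_update="jacobi", **kw).fit(Y, lncrna_sim=S_l, protein_sim=S_p)
        m2 = WGRMF(graph_update="exact", **kw).fit(Y, lncrna_sim=S_l, protein_sim=S_p)
        assert m1.objective_trace_[-1] == pytest.approx(
            m2.objective_trace_[-1], rel=1e-6
        )

    def test_parameter_validation(self, rng):
        Y = np.eye(3)
        with pytest.raises(ValueError):
            WGRMF(lambda_f=-1.0).fit(Y)
        with pytest.raises(ValueError):
            WGRMF(unknown_weight=2.0).fit(Y)
        with pytest.raises(ValueError):
            WGRMF(graph_update="bogus").fit(Y)
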