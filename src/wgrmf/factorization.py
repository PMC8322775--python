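"""Weighted graph-regularized matrix factorization (WGRMF).

The binary interaction matrix ``Y`` (n lncRNAs x m proteins) is completed
by latent factor matrices ``A`` (n x k) and ``B`` (m x k) minimizing the
weighted loss

    sum_ij W_ij (Y_ij - a_i . b_j)^2
      + lambda_f (||A||_F^2 + ||B||_F^2)
      + lambda_l Tr(A^T Lt_l A) + lambda_p Tr(B^T Lt_p B)

where ``W`` down-weights unobserved pairs (W_ij = 1 where Y_ij = 1, a
small ``unknown_weight`` elsewhere) and ``Lt_l`` / ``Lt_p`` are
symmetric-normalized Laplacians of the sparsified lncRNA / protein
similarity graphs.  The weights multiply the squared residuals (the
convention of weighted alternating least squares, under which the
row-wise update rules below are the exact per-row minimizers); for a
binary W this coincides with the masked Frobenius norm.  The solver
alternates row-wise ridge least-squares updates from a truncated-SVD
start; predicted interaction scores are ``A B^T``.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .graph import normalized_laplacian
from .io import InteractionMatrix

logger = logging.getLogger(__name__)


def svd_initialize(Y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-k start: ``A = U S_k^{1/2}``, ``B = V S_k^{1/2}`` from the
    truncated SVD of Y (unknown cells enter as 0)."""
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    if not 1 <= k <= min(n, m):
        raise ValueError("k must satisfy 1 <= k <= min(n, m)")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    root = np.sqrt(s[:k])
    return U[:, :k] * root, Vt[:k].T * root


def wgrmf_objective(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    W: np.ndarray,
    L_l: np.ndarray,
    L_p: np.ndarray,
    lambda_f: float,
    lambda_l: float,
    lambda_p: float,
) -> float:
    """Evaluate the weighted graph-regularized objective (weights multiply
    the squared residuals)."""
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("non-finite factor entries")
    R = Y - A @ B.T
    value = (
        float(np.sum(W * R * R))
        + lambda_f * (float(np.sum(A * A)) + float(np.sum(B * B)))
        + lambda_l * float(np.trace(A.T @ L_l @ A))
        + lambda_p * float(np.trace(B.T @ L_p @ B))
    )
    if not np.isfinite(value):
        raise ValueError("non-finite objective value")
    return value


def _row_solve(
    C: np.ndarray,
    F_other: np.ndarray,
    W: np.ndarray,
    F_old: np.ndarray,
    L: np.ndarray,
    lambda_f: float,
    lambda_graph: float,
) -> np.ndarray:
    """One Jacobi-style block update shared by both factor matrices.

    Row i of the result solves
        f_i (sum_j W_ij g_j g_j^T + lambda_f I) = C_i - lambda_graph (L F_old)_i
    where g_j are rows of ``F_other``; each k x k system is solved by a
    positive-definite linear solve (never an explicit inverse).
    """
    n, k = F_old.shape
    # batched Gram matrices: M[i] = F_other^T diag(W_i) F_other + lambda_f I
    M = np.einsum("ij,jk,jl->ikl", W, F_other, F_other, optimize=True)
    M += lambda_f * np.eye(k)[None, :, :]
    rhs = C - lambda_graph * (L @ F_old)
    if lambda_f == 0:
        # guard against singular Gram matrices
        out = np.empty_like(F_old)
        for i in range(n):
            out[i] = np.linalg.lstsq(M[i], rhs[i], rcond=None)[0]
        return out
    return np.linalg.solve(M, rhs[:, :, None])[:, :, 0]


def update_lncrna_factors(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    W: np.ndarray,
    L_l: np.ndarray,
    lambda_f: float,
    lambda_l: float,
) -> np.ndarray:
    """Ridge least-squares update of the lncRNA factors with B fixed; the
    graph term uses the pre-update A (Jacobi within the block)."""
    return _row_solve((W * Y) @ B, B, W, A, L_l, lambda_f, lambda_l)


def update_protein_factors(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    W: np.ndarray,
    L_p: np.ndarray,
    lambda_f: float,
    lambda_p: float,
) -> np.ndarray:
    """Mirror update of the protein factors with A fixed."""
    return _row_solve((W * Y).T @ A, A, W.T, B, L_p, lambda_f, lambda_p)


class WGRMF(BaseEstimator):
    """Weighted graph-regularized matrix factorization estimator.

    Parameters
    ----------
    n_components : int, default=50
        Latent rank k; capped at min(n, m) during fit.
    lambda_f : float, default=0.5
        Tikhonov (ridge) penalty on both factor matrices.
    lambda_l, lambda_p : float, default=0.3 and 0.005
        Graph-regularization strengths for the lncRNA and protein graphs.
    unknown_weight : float, default=0.1
        Weight of unobserved pairs in the data-fit term; 1 recovers
        unweighted GRMF, 0 ignores unknown pairs entirely.
    max_sweeps : int, default=100
        Alternating update budget (one sweep = A-update then B-update).
    tol : float, default=1e-6
        Relative objective-change stopping threshold.
    graph_update : {"jacobi", "exact"}, default="jacobi"
        "jacobi" takes one fixed-point step per block; "exact" solves each
        block subproblem to optimality with conjugate gradients.

    Attributes
    ----------
    A_ : ndarray of shape (n, k)
    B_ : ndarray of shape (m, k)
    objective_trace_ : list of float
        Objective after initialization and after every sweep.
    n_sweeps_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 50,
        lambda_f: float = 0.5,
        lambda_l: float = 0.3,
        lambda_p: float = 0.005,
        unknown_weight: float = 0.1,
        max_sweeps: int = 100,
        tol: float = 1e-6,
        graph_update: str = "jacobi",
    ):
        self.n_components = n_components
        self.lambda_f = lambda_f
        self.lambda_l = lambda_l
        self.lambda_p = lambda_p
        self.unknown_weight = unknown_weight
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.graph_update = graph_update

    # -- block solvers -------------------------------------------------

    def _exact_block(self, C, F_other, W, F_start, L, lambda_graph):
        """Solve the block normal equations (coupled across rows through
        the Laplacian) by conjugate gradients in factor-matrix space."""
        k = F_start.shape[1]
        M = np.einsum("ij,jk,jl->ikl", W, F_other, F_other, optimize=True)
        M += self.lambda_f * np.eye(k)[None, :, :]

        def op(F):
            return np.einsum("ikl,il->ik", M, F) + lambda_graph * (L @ F)

        F = F_start.copy()
        R = C - op(F)
        P = R.copy()
        rs = float(np.sum(R * R))
        scale = max(float(np.sum(C * C)), 1e-300)
        for _ in range(10 * F.size):
            if rs / scale < 1e-24:
                break
            Ap = op(P)
            alpha = rs / float(np.sum(P * Ap))
            F += alpha * P
            R -= alpha * Ap
            rs_new = float(np.sum(R * R))
            P = R + (rs_new / rs) * P
            rs = rs_new
        return F

    # -- estimator API -------------------------------------------------

    def fit(
        self,
        Y: np.ndarray | InteractionMatrix,
        lncrna_sim: np.ndarray | None = None,
        protein_sim: np.ndarray | None = None,
        W: np.ndarray | None = None,
    ) -> "WGRMF":
        """Fit latent factors to a binary interaction matrix.

        ``lncrna_sim`` / ``protein_sim`` are the (sparsified, symmetric)
        similarity matrices; their normalized Laplacians are built here.
        Omitting one disables the corresponding graph term.
        """
        if isinstance(Y, InteractionMatrix):
            self.lncrna_ids_ = list(Y.lncrna_ids)
            self.protein_ids_ = list(Y.protein_ids)
            Y = Y.values
        Y = np.asarray(Y, dtype=float)
        n, m = Y.shape
        for lam in (self.lambda_f, self.lambda_l, self.lambda_p):
            if lam < 0:
                raise ValueError("regularization strengths must be nonnegative")
        if not 0 <= self.unknown_weight <= 1:
            raise ValueError("unknown_weight must lie in [0, 1]")
        if self.graph_update not in ("jacobi", "exact"):
            raise ValueError("graph_update must be 'jacobi' or 'exact'")
        k = min(self.n_components, n, m)
        if k < self.n_components:
            logger.warning("rank capped at min(n, m) = %d", k)

        if W is None:
            W = np.where(Y == 1, 1.0, self.unknown_weight)
        else:
            W = np.asarray(W, dtype=float)
            if W.shape != Y.shape:
                raise ValueError("weight matrix shape mismatch")

        def laplacian_or_zero(S, size):
            if S is None:
                return np.zeros((size, size))
            S = np.asarray(S, dtype=float)
            if S.shape != (size, size):
                raise ValueError("similarity matrix shape mismatch")
            return normalized_laplacian(S)[1]

        L_l = laplacian_or_zero(lncrna_sim, n)
        L_p = laplacian_or_zero(protein_sim, m)

        A, B = svd_initialize(Y, k)
        obj = wgrmf_objective(
            Y, A, B, W, L_l, L_p, self.lambda_f, self.lambda_l, self.lambda_p
        )
        trace = [obj]
        converged = False
        prev_AB = (A.copy(), B.copy())
        for sweep in range(self.max_sweeps):
            if self.graph_update == "exact":
                A = self._exact_block((W * Y) @ B, B, W, A, L_l, self.lambda_l)
                B = self._exact_block((W * Y).T @ A, A, W.T, B, L_p, self.lambda_p)
            else:
                A = update_lncrna_factors(Y, A, B, W, L_l, self.lambda_f, self.lambda_l)
                B = update_protein_factors(Y, A, B, W, L_p, self.lambda_f, self.lambda_p)
            if not (np.isfinite(A).all() and np.isfinite(B).all()):
                # Jacobi fixed-point steps are not contractive when the
                # graph term dominates the data term; fall back to the
                # last finite iterate rather than propagating infinities.
                logger.warning(
                    "divergent update at sweep %d; reverting to previous "
                    "iterate (consider graph_update='exact' or smaller "
                    "graph penalties)", sweep + 1,
                )
                A, B = prev_AB
                break
            prev_AB = (A.copy(), B.copy())
            prev, obj = obj, wgrmf_objective(
                Y, A, B, W, L_l, L_p, self.lambda_f, self.lambda_l, self.lambda_p
            )
            trace.append(obj)
            logger.debug("sweep %d: objective %.6e", sweep + 1, obj)
            if abs(prev - obj) <= self.tol * max(abs(prev), 1e-300):
                converged = True
                break
        if not converged:
            logger.warning("WGRMF stopped at max_sweeps=%d", self.max_sweeps)

        self.A_, self.B_ = A, B
        self.W_ = W
        self.rank_ = k
        self.objective_trace_ = trace
        self.n_sweeps_ = len(trace) - 1
        self.converged_ = converged
        return self

    def predict(self) -> np.ndarray:
        """Interaction score matrix ``A B^T`` (real-valued, unclipped)."""
        if not hasattr(self, "A_"):
            raise AttributeError("model is not fitted")
        return self.A_ @ self.B_.T
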