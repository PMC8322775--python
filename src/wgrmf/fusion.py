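"""Similarity kernel fusion (SKF).

Multiple similarity kernels over the same entities are merged into one
consensus kernel by cross-diffusion: each kernel is column-normalized
(the global view) and row-normalized over its k nearest neighbors (the
local view); the global views are then iteratively diffused through the
local views of the other kernels,

    Theta_q(t+1) = alpha/2 * phi_q (sum_{r != q} Theta_r(t)) phi_q^T
                   + (1 - alpha)/2 * sum_{r != q} Theta_r(0),

averaged after convergence, and finally down-weighted where the kernels'
k-NN structures disagree: the agreement weight is 1 where every kernel
lists j among i's k nearest neighbors, 0 where none does, 0.5 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class FusedSimilarity:
    """Consensus kernel with its fusion intermediates."""

    ids: list[str]
    final: np.ndarray          # agreement-weighted, symmetrized consensus
    theta: np.ndarray          # diffused average before weighting
    weights: np.ndarray        # k-NN agreement weights in {0, 0.5, 1}
    n_iterations: int
    alpha: float
    n_neighbors: int


def column_normalize(S: np.ndarray) -> np.ndarray:
    """Normalize each column to sum 1; all-zero columns stay zero."""
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("negative entries in similarity kernel")
    sums = S.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("%d all-zero columns left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, sums)
    return S / safe[None, :]


def knn_indicator(S: np.ndarray, k: int) -> np.ndarray:
    """Boolean matrix: entry (i, j) true iff j is among the k most similar
    entities to i (self excluded; similarity ties broken by id order)."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n")
    ind = np.zeros((n, n), dtype=bool)
    for i in range(n):
        s = S[i].copy()
        s[i] = -np.inf
        order = np.lexsort((np.arange(n), -s))
        ind[i, order[:k]] = True
    return ind


def neighborhood_normalize(S: np.ndarray, k: int) -> np.ndarray:
    """Row-normalize a kernel restricted to each row's k nearest neighbors."""
    S = np.asarray(S, dtype=float)
    masked = S * knn_indicator(S, k)
    sums = masked.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("%d rows with zero neighbor mass", int(zero.sum()))
    safe = np.where(zero, 1.0, sums)
    return masked / safe[:, None]


class SimilarityKernelFusion(BaseEstimator, TransformerMixin):
    """Fuse a list of similarity kernels into one consensus kernel.

    Parameters
    ----------
    alpha : float, default=0.5
        Diffusion weight in (0, 1) balancing the iterated term against the
        initial kernels.
    n_neighbors : int, default=7
        Neighborhood size for both the local views and the agreement
        weights.
    max_iter : int, default=20
        Diffusion iteration budget; ``max_iter=0`` returns the plain
        average of the column-normalized kernels.
    tol : float, default=1e-6
        Relative Frobenius-change stopping threshold.

    Attributes
    ----------
    fused_ : FusedSimilarity
    n_iter_ : int
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_neighbors: int = 7,
        max_iter: int = 20,
        tol: float = 1e-6,
    ):
        self.alpha = alpha
        self.n_neighbors = n_neighbors
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, kernels: list[np.ndarray], y=None, ids: list[str] | None = None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        mats = [np.asarray(K, dtype=float) for K in kernels]
        if not mats:
            raise ValueError("no kernels to fuse")
        n = mats[0].shape[0]
        for K in mats:
            if K.shape != (n, n):
                raise ValueError("kernels differ in shape")
        if ids is None:
            ids = [str(i) for i in range(n)]

        if len(mats) == 1:
            logger.warning("single kernel supplied; fusion is the identity")
            final = (mats[0] + mats[0].T) / 2.0
            self.fused_ = FusedSimilarity(
                list(ids), final, mats[0].copy(), np.ones((n, n)), 0,
                self.alpha, self.n_neighbors,
            )
            self.n_iter_ = 0
            return self
        if len(mats) < 3:
            logger.warning("fusing %d kernels (expected 3)", len(mats))

        theta0 = [column_normalize(K) for K in mats]
        phi = [neighborhood_normalize(K, self.n_neighbors) for K in mats]
        cur = [T.copy() for T in theta0]
        n_iter = 0
        for _ in range(self.max_iter):
            nxt = []
            for q in range(len(cur)):
                others_cur = sum(cur[r] for r in range(len(cur)) if r != q)
                others_init = sum(theta0[r] for r in range(len(cur)) if r != q)
                nxt.append(
                    0.5 * self.alpha * (phi[q] @ others_cur @ phi[q].T)
                    + 0.5 * (1.0 - self.alpha) * others_init
                )
            delta = max(
                np.linalg.norm(b - a, "fro") / max(np.linalg.norm(a, "fro"), 1e-300)
                for a, b in zip(cur, nxt)
            )
            cur = nxt
            n_iter += 1
            logger.debug("SKF iteration %d: delta=%.3e", n_iter, delta)
            if delta < self.tol:
                break
        else:
            if self.max_iter > 0:
                logger.warning(
                    "SKF stopped at max_iter=%d without meeting tol", self.max_iter
                )

        theta = sum(cur) / len(cur)
        indicators = np.stack([knn_indicator(K, self.n_neighbors) for K in mats])
        all_in = indicators.all(axis=0)
        none_in = (~indicators).all(axis=0)
        weights = np.where(all_in, 1.0, np.where(none_in, 0.0, 0.5))
        final = theta * weights
        final = (final + final.T) / 2.0
        self.fused_ = FusedSimilarity(
            list(ids), final, theta, weights, n_iter, self.alpha, self.n_neighbors
        )
        self.n_iter_ = n_iter
        return self

    def transform(self, kernels) -> np.ndarray:
        del kernels
        return self.fused_.final

    def fit_transform(self, kernels, y=None, **fit_params) -> np.ndarray:
        return self.fit(kernels, **fit_params).fused_.final


def skf_fuse(
    kernels: list[np.ndarray],
    alpha: float = 0.5,
    k: int = 7,
    max_iter: int = 20,
    tol: float = 1e-6,
    ids: list[str] | None = None,
) -> FusedSimilarity:
    """Functional wrapper over :class:`SimilarityKernelFusion`."""
    est = SimilarityKernelFusion(alpha=alpha, n_neighbors=k, max_iter=max_iter, tol=tol)
    return est.fit(kernels, ids=ids).fused_
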