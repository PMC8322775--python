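"""p-nearest-neighbor sparsification and graph Laplacians.

The fused similarity matrix is sparsified through a p-NN mask that keeps
mutual neighbors at full weight, one-sided neighbors at half weight, and
drops the rest; the Laplacian of the sparsified graph is the regularizer
that pulls neighboring entities' latent vectors together during the
factorization.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


def pnn_mask(S: np.ndarray, p: int) -> np.ndarray:
    """Mutual/one-sided p-nearest-neighbor mask.

    ``N_ij = 1`` when i and j are in each other's p-NN sets, 0 when
    neither is, 0.5 otherwise; the diagonal is 1.  Similarity ties at the
    p-th rank are broken by id order.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= p < n:
        raise ValueError("p must satisfy 1 <= p < n")
    member = np.zeros((n, n), dtype=bool)  # member[i, j]: j in N_p(i)
    for i in range(n):
        s = S[i].copy()
        s[i] = -np.inf
        order = np.lexsort((np.arange(n), -s))
        member[i, order[:p]] = True
    both = member & member.T
    neither = ~member & ~member.T
    mask = np.where(both, 1.0, np.where(neither, 0.0, 0.5))
    np.fill_diagonal(mask, 1.0)
    return mask


def sparsify(S: np.ndarray, mask: np.ndarray, resymmetrize: bool = True) -> np.ndarray:
    """Elementwise product of similarity and mask; re-symmetrized by mean
    to guard against tie-break asymmetries."""
    S = np.asarray(S, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if S.shape != mask.shape:
        raise ValueError("similarity and mask shapes differ")
    out = S * mask
    if resymmetrize:
        out = (out + out.T) / 2.0
    return out


def normalized_laplacian(S_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Graph Laplacian ``L = D - S`` and its symmetric normalization
    ``D^{-1/2} L D^{-1/2}`` (zero-degree nodes get zero rows/columns)."""
    S_hat = np.asarray(S_hat, dtype=float)
    if (S_hat < 0).any():
        raise ValueError("similarity entries must be nonnegative")
    deg = S_hat.sum(axis=1)
    L = np.diag(deg) - S_hat
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L_tilde = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    return L, L_tilde


class NearestNeighborSparsifier(BaseEstimator, TransformerMixin):
    """Sparsify a similarity matrix through its p-NN graph.

    Attributes
    ----------
    mask_ : ndarray
        The {0, 0.5, 1} p-NN mask.
    sparse_similarity_ : ndarray
    laplacian_, normalized_laplacian_ : ndarray
    """

    def __init__(self, p: int = 7):
        self.p = p

    def fit(self, S: np.ndarray, y=None) -> "NearestNeighborSparsifier":
        self.mask_ = pnn_mask(S, self.p)
        self.sparse_similarity_ = sparsify(S, self.mask_)
        self.laplacian_, self.normalized_laplacian_ = normalized_laplacian(
            self.sparse_similarity_
        )
        return self

    def transform(self, S: np.ndarray) -> np.ndarray:
        del S
        return self.sparse_similarity_

    def fit_transform(self, S: np.ndarray, y=None, **fit_params) -> np.ndarray:
        return self.fit(S).sparse_similarity_
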