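"""Fixed-length sequence descriptors and linear-neighborhood similarity.

lncRNAs are described by normalized mono- plus di-nucleotide composition
(4 + 16 = 20 dimensions).  Proteins use grouped k-mer composition over the
seven conjoint-triad physicochemical classes for k in {1, 2, 3}
(7 + 49 + 343 = 399 dimensions by default; the grouping and k range are
configurable).  Each k-block of a descriptor sums to 1 for sequences long
enough to contain at least one k-mer.

Linear-neighborhood similarity (LNS) reconstructs each feature vector as a
convex combination of its nearest neighbors: for entity i with neighbor set
N(i) it solves

    min_w  || x_i - sum_{j in N(i)} w_j x_j ||^2 + reg * ||w||^2
    s.t.   w_j >= 0,  sum_j w_j = 1

and uses the optimal weights as (asymmetric) similarities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMBIGUOUS_AA_MAP, SequenceSet

#: conjoint-triad amino-acid classes (dipole / side-chain volume groups)
CONJOINT_TRIAD_GROUPS: tuple[str, ...] = (
    "AGV",
    "ILFP",
    "YMTS",
    "HNQW",
    "RK",
    "DE",
    "C",
)

RNA_LETTERS = "ACGU"


@dataclass
class FeatureVectorSet:
    """Equal-length real descriptors, one row per entity."""

    ids: list[str]
    vectors: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("id count does not match vector rows")
        if len(self.feature_names) != self.vectors.shape[1]:
            raise ValueError("feature name count does not match dimension")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite feature values")


def _kmer_block(seq: str, alphabet: str, k: int) -> np.ndarray:
    """Normalized k-mer frequencies over ``alphabet`` in lexicographic order."""
    index = {c: i for i, c in enumerate(alphabet)}
    a = len(alphabet)
    counts = np.zeros(a**k)
    for start in range(len(seq) - k + 1):
        code = 0
        for c in seq[start : start + k]:
            code = code * a + index[c]
        counts[code] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def lncrna_features(seqs: SequenceSet) -> FeatureVectorSet:
    """20-dimensional composition descriptor: mono- then di-nucleotide
    frequencies, each block normalized to sum 1."""
    if seqs.alphabet != "rna":
        raise ValueError("lncrna_features expects an RNA SequenceSet")
    names = list(RNA_LETTERS) + [
        a + b for a, b in itertools.product(RNA_LETTERS, repeat=2)
    ]
    rows = []
    for sid, seq in zip(seqs.ids, seqs.sequences):
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
        rows.append(
            np.concatenate([_kmer_block(seq, RNA_LETTERS, 1), _kmer_block(seq, RNA_LETTERS, 2)])
        )
    return FeatureVectorSet(list(seqs.ids), np.vstack(rows), names)


def _group_sequence(
    seq: str, groups: tuple[str, ...], ambiguous_map: dict[str, str]
) -> str:
    """Rewrite an amino-acid sequence as a string of group indices."""
    lookup: dict[str, str] = {}
    for gi, members in enumerate(groups):
        for aa in members:
            lookup[aa] = chr(ord("0") + gi)
    out = []
    for c in seq:
        c = ambiguous_map.get(c, c)
        if c not in lookup:
            raise ValueError(f"amino acid {c!r} not covered by the group scheme")
        out.append(lookup[c])
    return "".join(out)


def protein_features(
    seqs: SequenceSet,
    groups: tuple[str, ...] = CONJOINT_TRIAD_GROUPS,
    k_values: tuple[int, ...] = (1, 2, 3),
    ambiguous_map: dict[str, str] | None = None,
) -> FeatureVectorSet:
    """Grouped k-mer composition descriptor over physicochemical classes.

    With the default 7 conjoint-triad groups and k in {1,2,3} the descriptor
    has 7 + 49 + 343 = 399 dimensions; each k-block sums to 1.
    """
    if seqs.alphabet != "protein":
        raise ValueError("protein_features expects a protein SequenceSet")
    if ambiguous_map is None:
        ambiguous_map = AMBIGUOUS_AA_MAP
    g = len(groups)
    group_alphabet = "".join(chr(ord("0") + i) for i in range(g))
    names = []
    for k in k_values:
        names += [
            "g" + "".join(t) for t in itertools.product(group_alphabet, repeat=k)
        ]
    rows = []
    for sid, seq in zip(seqs.ids, seqs.sequences):
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
        gs = _group_sequence(seq, groups, ambiguous_map)
        rows.append(
            np.concatenate([_kmer_block(gs, group_alphabet, k) for k in k_values])
        )
    return FeatureVectorSet(list(seqs.ids), np.vstack(rows), names)


def _simplex_lsq(neighbors: np.ndarray, x: np.ndarray, reg: float) -> np.ndarray:
    """Exact nonnegative least squares on the probability simplex.

    Minimizes ||x - N^T w||^2 + reg ||w||^2 subject to w >= 0, sum w = 1 by
    enumerating active sets and checking the KKT conditions; falls back to
    the feasible candidate with the lowest objective when rounding blurs the
    dual test.  Exponential in the neighbor count, which is small (<= ~12).
    """
    K = neighbors.shape[0]
    G = neighbors @ neighbors.T + reg * np.eye(K)
    c = neighbors @ x

    def objective(w: np.ndarray) -> float:
        return float(w @ G @ w - 2 * c @ w)

    best_kkt: np.ndarray | None = None
    best_feasible: tuple[float, np.ndarray] | None = None
    for size in range(1, K + 1):
        for support in itertools.combinations(range(K), size):
            S = list(support)
            # equality-constrained stationarity: 2 G_S w - 2 c_S = nu * 1
            A = np.zeros((size + 1, size + 1))
            A[:size, :size] = 2 * G[np.ix_(S, S)]
            A[:size, size] = -1.0
            A[size, :size] = 1.0
            b = np.zeros(size + 1)
            b[:size] = 2 * c[S]
            b[size] = 1.0
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            w_s, nu = sol[:size], sol[size]
            if (w_s < -1e-10).any():
                continue
            w = np.zeros(K)
            w[S] = np.clip(w_s, 0.0, None)
            w /= w.sum()
            if best_feasible is None or objective(w) < best_feasible[0]:
                best_feasible = (objective(w), w)
            grad = 2 * (G @ w - c)
            if ((grad - nu)[np.setdiff1d(np.arange(K), S)] >= -1e-9).all():
                if best_kkt is None or objective(w) < objective(best_kkt):
                    best_kkt = w
        if best_kkt is not None:
            break  # smallest KKT-valid support wins; larger ones tie or lose
    if best_kkt is not None:
        return best_kkt
    assert best_feasible is not None  # simplex is nonempty
    return best_feasible[1]


class LinearNeighborhoodSimilarity(TransformerMixin, BaseEstimator):
    """Linear-neighborhood similarity over a feature matrix.

    Parameters
    ----------
    n_neighbors : int, default=5
        Neighbors used to reconstruct each vector (Euclidean distance;
        distance ties broken by row order).
    reg : float, default=1e-3
        Ridge term stabilizing the reconstruction weights.

    Attributes
    ----------
    similarity_ : ndarray of shape (n, n)
        Row i holds the reconstruction weights of entity i on its
        neighbors; zero elsewhere and on the diagonal.  Rows sum to 1.
    """

    def __init__(self, n_neighbors: int = 5, reg: float = 1e-3):
        self.n_neighbors = n_neighbors
        self.reg = reg

    def fit(self, X: np.ndarray, y=None) -> "LinearNeighborhoodSimilarity":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        if not 1 <= self.n_neighbors < n:
            raise ValueError("n_neighbors must satisfy 1 <= k < n")
        if self.reg <= 0:
            raise ValueError("reg must be positive")
        S = np.zeros((n, n))
        for i in range(n):
            d = np.linalg.norm(X - X[i], axis=1)
            d[i] = np.inf
            order = np.lexsort((np.arange(n), d))  # ties by id order
            nbrs = order[: self.n_neighbors]
            w = _simplex_lsq(X[nbrs], X[i], self.reg)
            S[i, nbrs] = w
        self.similarity_ = S
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        del X
        return self.similarity_

    def fit_transform(self, X: np.ndarray, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).similarity_


def linear_neighborhood_similarity(
    feats: FeatureVectorSet, n_neighbors: int = 5, reg: float = 1e-3
) -> np.ndarray:
    """Functional wrapper over :class:`LinearNeighborhoodSimilarity`."""
    return LinearNeighborhoodSimilarity(n_neighbors, reg).fit_transform(feats.vectors)
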