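"""Per-source similarity kernels for lncRNAs and proteins.

Three kernel families feed the fusion stage:

* expression similarity — rescaled Pearson correlation of expression
  profiles, ``s(i,j) = (1 + rho_ij) / 2`` off the diagonal, 0 on it;
* interaction-profile similarity — a Gaussian kernel on rows (lncRNAs) or
  columns (proteins) of the binary interaction matrix,
  ``s(i,j) = exp(-||Y_i - Y_j||^2 / gamma)`` with ``gamma`` the mean
  squared profile norm;
* alignment similarity — Smith-Waterman local-alignment score of protein
  ``u`` against ``v`` normalized by the self-score of ``u``, diagonal 0,
  then symmetrized by arithmetic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import squareform, pdist

from .io import AMBIGUOUS_AA_MAP, ExpressionProfileSet, InteractionMatrix, SequenceSet

logger = logging.getLogger(__name__)


@dataclass
class SimilarityKernel:
    """Square nonnegative similarity matrix over one entity type."""

    ids: list[str]
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("kernel must be square")
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("kernel dimension does not match id count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("kernel has non-finite entries")
        if (self.matrix < 0).any():
            raise ValueError("kernel has negative entries")


def expression_similarity(profiles: ExpressionProfileSet) -> SimilarityKernel:
    """Pearson-correlation similarity of expression profiles.

    Zero-variance profiles get correlation 0 against everything
    (similarity 0.5) with a warning rather than propagating NaN.
    """
    X = profiles.profiles
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance expression profiles", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X)
    rho = np.atleast_2d(rho)
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0
    S = (1.0 + rho) / 2.0
    np.fill_diagonal(S, 0.0)
    return SimilarityKernel(list(profiles.lncrna_ids), np.clip(S, 0.0, 1.0), "expression")


def interaction_profile_similarity(
    Y: InteractionMatrix, axis: str = "lncrna"
) -> SimilarityKernel:
    """Gaussian interaction-profile kernel on rows or columns of Y.

    The bandwidth ``gamma`` is the mean squared norm of the profiles on the
    chosen axis, so the kernel adapts to interaction density.
    """
    if axis == "lncrna":
        P = Y.values
        ids = Y.lncrna_ids
    elif axis == "protein":
        P = Y.values.T
        ids = Y.protein_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    gamma = float(np.mean(np.sum(P**2, axis=1)))
    if gamma == 0:
        raise ValueError("degenerate interaction matrix: no known interactions")
    if P.shape[0] > 1:
        D2 = squareform(pdist(P, metric="sqeuclidean"))
    else:
        D2 = np.zeros((1, 1))
    return SimilarityKernel(list(ids), np.exp(-D2 / gamma), f"interaction_profile_{axis}")


def _make_aligner(
    matrix_name: str, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def smith_waterman_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal local-alignment score under an affine gap model."""
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    return float(aligner.score(a, b))


def alignment_similarity(
    seqs: SequenceSet,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    symmetrize: bool = True,
) -> SimilarityKernel:
    """Normalized Smith-Waterman similarity between protein sequences.

    ``s(u,v) = b_uv / b_uu`` for u != v with ``b`` the local-alignment
    score; the diagonal is 0.  Because the raw ratio matrix is asymmetric
    (it normalizes by the self-score of the first sequence only) it is
    symmetrized by arithmetic mean unless ``symmetrize=False``.
    """
    if seqs.alphabet != "protein":
        raise ValueError("alignment_similarity expects protein sequences")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    legal = set(str(aligner.substitution_matrix.alphabet))
    clean = [
        "".join(AMBIGUOUS_AA_MAP.get(c, c) if c not in legal else c for c in s)
        for s in seqs.sequences
    ]
    n = len(clean)
    b = np.zeros((n, n))
    for u in range(n):
        for v in range(u, n):
            b[u, v] = b[v, u] = aligner.score(clean[u], clean[v])
    self_scores = np.diag(b).copy()
    if (self_scores <= 0).any():
        raise ValueError("sequence with non-positive self-alignment score")
    S = b / self_scores[:, None]
    np.fill_diagonal(S, 0.0)
    if symmetrize:
        S = (S + S.T) / 2.0
    return SimilarityKernel(list(seqs.ids), S, "alignment")
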