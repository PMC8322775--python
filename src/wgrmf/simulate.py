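"""Seed-controlled synthetic lncRNA-protein interaction scenarios.

A scenario plants low-rank structure: latent factors ``A*`` (lncRNAs) and
``B*`` (proteins) are drawn with standard-normal entries, the continuous
affinity ``A* B*^T`` is binarized at the quantile giving the requested
interaction density, and labels are optionally flipped with a noise
probability.  Side data are emitted so that every similarity source
carries signal about the planted factors:

* lncRNA sequences — nucleotides sampled from per-entity letter
  probabilities ``softmax(M_l a*_i)`` for a fixed random projection;
* protein sequences — amino acids sampled analogously from
  ``softmax(M_p b*_u)``;
* expression profiles — noisy linear images ``A* G + eps`` of the lncRNA
  factors across samples.

Scenarios serialize to the same FASTA/TSV dialects the readers consume,
so fixtures exercise the real I/O path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    ExpressionProfileSet,
    InteractionMatrix,
    SequenceSet,
    write_expression,
    write_fasta,
    write_interactions,
)

RNA_LETTERS = "ACGU"
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticScenario:
    """One generated study condition with its ground truth."""

    interactions: InteractionMatrix
    affinity: np.ndarray
    lncrna_factors: np.ndarray
    protein_factors: np.ndarray
    lncrna_sequences: SequenceSet
    protein_sequences: SequenceSet
    expression: ExpressionProfileSet
    params: dict
    seed: int


def _emission_sequences(
    factors: np.ndarray,
    letters: str,
    length: int,
    prefix: str,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> SequenceSet:
    """Sample per-entity sequences from softmax(M f) letter probabilities."""
    n, r = factors.shape
    M = rng.standard_normal((len(letters), r)) / np.sqrt(r)
    logits = temperature * factors @ M.T
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    seqs = [
        "".join(rng.choice(list(letters), size=length, p=probs[i])) for i in range(n)
    ]
    alphabet = "rna" if letters == RNA_LETTERS else "protein"
    return SequenceSet(ids, seqs, alphabet)


def generate_scenario(
    n: int = 60,
    m: int = 60,
    rank_true: int = 4,
    density: float = 0.15,
    noise: float = 0.0,
    seed: int = 0,
    lncrna_seq_length: int = 200,
    protein_seq_length: int = 100,
    n_samples: int = 30,
    expression_noise: float = 0.5,
) -> SyntheticScenario:
    """Generate one synthetic scenario (bit-identical given the seed)."""
    if rank_true > min(n, m):
        raise ValueError("rank_true must not exceed min(n, m)")
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    if not 0 <= noise < 0.5:
        raise ValueError("noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    A_true = rng.standard_normal((n, rank_true))
    B_true = rng.standard_normal((m, rank_true))
    affinity = A_true @ B_true.T

    n_pos = int(round(density * n * m))
    flat = affinity.ravel()
    order = np.argsort(-flat, kind="stable")  # ties broken by cell order
    Y = np.zeros(n * m)
    Y[order[:n_pos]] = 1.0
    Y = Y.reshape(n, m)
    if noise > 0:
        flips = rng.random((n, m)) < noise
        Y = np.where(flips, 1.0 - Y, Y)

    lnc_seqs = _emission_sequences(A_true, RNA_LETTERS, lncrna_seq_length, "LNC", rng)
    prot_seqs = _emission_sequences(B_true, AA_LETTERS, protein_seq_length, "PRO", rng)
    G = rng.standard_normal((rank_true, n_samples))
    expr = A_true @ G + expression_noise * rng.standard_normal((n, n_samples))
    expression = ExpressionProfileSet(list(lnc_seqs.ids), expr)

    interactions = InteractionMatrix(list(lnc_seqs.ids), list(prot_seqs.ids), Y)
    params = {
        "n": n, "m": m, "rank_true": rank_true, "density": density,
        "noise": noise, "lncrna_seq_length": lncrna_seq_length,
        "protein_seq_length": protein_seq_length, "n_samples": n_samples,
        "expression_noise": expression_noise,
    }
    return SyntheticScenario(
        interactions, affinity, A_true, B_true, lnc_seqs, prot_seqs,
        expression, params, seed,
    )


def degrade(
    scenario: SyntheticScenario, hide_fraction: float = 0.2, seed: int = 0
) -> tuple[InteractionMatrix, list[tuple[int, int]]]:
    """Hide a uniform random fraction of positives for recovery scoring.

    Returns the masked training matrix and the list of hidden (row,
    column) index pairs.
    """
    if not 0 < hide_fraction < 1:
        raise ValueError("hide_fraction must lie in (0, 1)")
    values = scenario.interactions.values.copy()
    pos = np.argwhere(values == 1)
    n_hide = int(round(hide_fraction * len(pos)))
    if n_hide >= len(pos):
        raise ValueError("hiding would remove every positive")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pos), size=n_hide, replace=False)
    hidden = [tuple(p) for p in pos[picked]]
    for i, j in hidden:
        values[i, j] = 0.0
    train = InteractionMatrix(
        list(scenario.interactions.lncrna_ids),
        list(scenario.interactions.protein_ids),
        values,
    )
    return train, hidden


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a scenario to the on-disk formats the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out_dir / "interactions.tsv",
        "lncrna_fasta": out_dir / "lncrna.fasta",
        "protein_fasta": out_dir / "protein.fasta",
        "expression": out_dir / "expression.tsv",
    }
    write_interactions(scenario.interactions, paths["interactions"], dialect="dense")
    write_fasta(scenario.lncrna_sequences, paths["lncrna_fasta"])
    write_fasta(scenario.protein_sequences, paths["protein_fasta"])
    write_expression(scenario.expression, paths["expression"])
    return paths
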