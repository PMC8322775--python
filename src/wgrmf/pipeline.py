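"""End-to-end orchestration: kernels -> fusion -> sparsification -> fit.

This is the programmatic counterpart of the CLI: it builds the per-source
kernels from whatever inputs are available (sequences, expression,
interaction profiles), fuses each entity type's kernels, sparsifies the
consensus through the p-NN graph, and fits the weighted
graph-regularized factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import compute_metrics
from .factorization import WGRMF
from .features import (
    linear_neighborhood_similarity,
    lncrna_features,
    protein_features,
)
from .fusion import skf_fuse
from .graph import NearestNeighborSparsifier
from .io import ExpressionProfileSet, InteractionMatrix, SequenceSet
from .similarity import (
    SimilarityKernel,
    alignment_similarity,
    expression_similarity,
    interaction_profile_similarity,
)
from .simulate import SyntheticScenario, degrade, generate_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Hyper-parameters of the full pipeline (defaults are the reported
    best combination: k=50, p=7, lambda_f=0.5, lambda_l=0.3,
    lambda_p=0.005)."""

    n_components: int = 50
    p_neighbors: int = 7
    lambda_f: float = 0.5
    lambda_l: float = 0.3
    lambda_p: float = 0.005
    unknown_weight: float = 0.1
    alpha: float = 0.5
    fusion_neighbors: int = 7
    fusion_max_iter: int = 20
    fusion_tol: float = 1e-6
    lns_neighbors: int = 5
    lns_reg: float = 1e-3
    max_sweeps: int = 100
    tol: float = 1e-6
    graph_update: str = "jacobi"
    extra: dict = field(default_factory=dict)


def build_lncrna_kernels(
    Y: InteractionMatrix,
    sequences: SequenceSet | None = None,
    expression: ExpressionProfileSet | None = None,
    config: PipelineConfig | None = None,
) -> list[SimilarityKernel]:
    """Base lncRNA kernels: sequence-statistics LNS, expression, and
    interaction-profile.  Missing inputs reduce the list with a warning;
    the interaction-profile kernel is always available."""
    config = config or PipelineConfig()
    kernels: list[SimilarityKernel] = []
    if sequences is not None:
        feats = lncrna_features(sequences.subset(Y.lncrna_ids))
        kernels.append(
            SimilarityKernel(
                Y.lncrna_ids,
                linear_neighborhood_similarity(
                    feats, config.lns_neighbors, config.lns_reg
                ),
                "seq_stat_lncrna",
            )
        )
    else:
        logger.warning("no lncRNA sequences: sequence-statistics kernel skipped")
    if expression is not None:
        kernels.append(expression_similarity(expression.align_to(Y.lncrna_ids)))
    else:
        logger.warning("no expression profiles: expression kernel skipped")
    kernels.append(interaction_profile_similarity(Y, axis="lncrna"))
    return kernels


def build_protein_kernels(
    Y: InteractionMatrix,
    sequences: SequenceSet | None = None,
    config: PipelineConfig | None = None,
) -> list[SimilarityKernel]:
    """Base protein kernels: alignment ratio, sequence-feature LNS, and
    interaction-profile."""
    config = config or PipelineConfig()
    kernels: list[SimilarityKernel] = []
    if sequences is not None:
        sub = sequences.subset(Y.protein_ids)
        kernels.append(alignment_similarity(sub))
        feats = protein_features(sub)
        kernels.append(
            SimilarityKernel(
                Y.protein_ids,
                linear_neighborhood_similarity(
                    feats, config.lns_neighbors, config.lns_reg
                ),
                "seq_stat_protein",
            )
        )
    else:
        logger.warning("no protein sequences: alignment and feature kernels skipped")
    kernels.append(interaction_profile_similarity(Y, axis="protein"))
    return kernels


def fuse_and_sparsify(
    kernels: list[SimilarityKernel], config: PipelineConfig
) -> np.ndarray:
    """SKF consensus of the kernels, sparsified through the p-NN graph."""
    n = kernels[0].matrix.shape[0]
    fusion_k = min(config.fusion_neighbors, n - 1)
    fused = skf_fuse(
        [K.matrix for K in kernels],
        alpha=config.alpha,
        k=fusion_k,
        max_iter=config.fusion_max_iter,
        tol=config.fusion_tol,
        ids=kernels[0].ids,
    )
    sparsifier = NearestNeighborSparsifier(p=min(config.p_neighbors, n - 1))
    return sparsifier.fit_transform(fused.final)


def fit_predict(
    Y: InteractionMatrix,
    lncrna_sequences: SequenceSet | None = None,
    protein_sequences: SequenceSet | None = None,
    expression: ExpressionProfileSet | None = None,
    config: PipelineConfig | None = None,
) -> tuple[WGRMF, np.ndarray]:
    """Run the full pipeline on one interaction matrix; returns the fitted
    model and the dense score matrix."""
    config = config or PipelineConfig()
    S_l = fuse_and_sparsify(
        build_lncrna_kernels(Y, lncrna_sequences, expression, config), config
    )
    S_p = fuse_and_sparsify(
        build_protein_kernels(Y, protein_sequences, config), config
    )
    model = WGRMF(
        n_components=config.n_components,
        lambda_f=config.lambda_f,
        lambda_l=config.lambda_l,
        lambda_p=config.lambda_p,
        unknown_weight=config.unknown_weight,
        max_sweeps=config.max_sweeps,
        tol=config.tol,
        graph_update=config.graph_update,
    )
    model.fit(Y, lncrna_sim=S_l, protein_sim=S_p)
    return model, model.predict()


def recovery_experiment(
    n: int = 60,
    m: int = 60,
    rank_true: int = 4,
    density: float = 0.15,
    noise: float = 0.0,
    hide_fraction: float = 0.2,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Hidden-positive recovery on one synthetic scenario.

    Generates a scenario, hides a fraction of the positives, runs the full
    pipeline on the degraded matrix, and scores the hidden positives
    against the remaining unknown pairs (pairs still positive in training
    are excluded from ranking).
    """
    scenario = generate_scenario(
        n=n, m=m, rank_true=rank_true, density=density, noise=noise, seed=seed
    )
    return recover_hidden(scenario, hide_fraction=hide_fraction, seed=seed + 1,
                          config=config)


def recover_hidden(
    scenario: SyntheticScenario,
    hide_fraction: float = 0.2,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Degrade a scenario and measure how well the pipeline re-ranks the
    hidden positives among unknown pairs."""
    train, hidden = degrade(scenario, hide_fraction=hide_fraction, seed=seed)
    _, scores = fit_predict(
        train,
        lncrna_sequences=scenario.lncrna_sequences,
        protein_sequences=scenario.protein_sequences,
        expression=scenario.expression,
        config=config,
    )
    eval_mask = train.values == 0  # hidden positives + true unknowns
    truth = np.zeros_like(train.values)
    for i, j in hidden:
        truth[i, j] = 1.0
    report = compute_metrics(scores[eval_mask], truth[eval_mask])
    return {
        "auc": report.auc,
        "aupr": report.aupr,
        "n_hidden": float(len(hidden)),
        "n_evaluated": float(eval_mask.sum()),
    }
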