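"""Cross-validation, ranking metrics and candidate ranking.

The primary metrics are AUC (area under the ROC curve, computed as the
Mann-Whitney rank statistic) and AUPR (area under the precision-recall
curve by step integration).  Thresholded metrics (precision, recall,
accuracy, F1) are reported at a configurable threshold policy; the default
rescales scores to [0, 1] by min-max and thresholds at 0.5.

Three cross-validation schemes are supported: ``pairwise`` masks a fifth
of the known positive pairs per fold, ``lncrna_rows`` and
``protein_columns`` hold out whole entities.  All unknown pairs in the
test region act as negatives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import InteractionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Cross-validation protocol description."""

    n_folds: int = 5
    repeats: int = 20
    scheme: str = "pairwise"  # pairwise | lncrna_rows | protein_columns
    seed: int = 0
    negative_policy: str = "all"  # all | matched

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.scheme not in ("pairwise", "lncrna_rows", "protein_columns"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.negative_policy not in ("all", "matched"):
            raise ValueError(f"unknown negative policy {self.negative_policy!r}")


@dataclass
class MetricReport:
    """Mean metrics with the per-fold table they aggregate."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    aupr: float
    threshold: float
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "aupr": self.aupr,
        }


def make_folds(
    Y: InteractionMatrix | np.ndarray, plan: CVPlan
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Boolean (train_mask, test_mask) pairs per repeat and fold.

    Under the pairwise scheme each repeat partitions the known positives
    into ``n_folds`` disjoint test sets; the test mask additionally carries
    the negative pairs dictated by ``negative_policy``.  Row/column schemes
    partition whole lncRNAs/proteins instead.  Deterministic given the
    plan's seed.
    """
    values = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y)
    n, m = values.shape
    pos = np.argwhere(values == 1)
    if len(pos) < plan.n_folds and plan.scheme == "pairwise":
        raise ValueError("fewer positives than folds")
    rng = np.random.default_rng(plan.seed)
    out: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for _ in range(plan.repeats):
        folds: list[tuple[np.ndarray, np.ndarray]] = []
        if plan.scheme == "pairwise":
            order = rng.permutation(len(pos))
            chunks = np.array_split(order, plan.n_folds)
            neg = np.argwhere(values == 0)
            for chunk in chunks:
                test = np.zeros((n, m), dtype=bool)
                held = pos[chunk]
                test[held[:, 0], held[:, 1]] = True
                if plan.negative_policy == "all":
                    test[values == 0] = True
                else:
                    pick = rng.choice(len(neg), size=min(len(chunk), len(neg)), replace=False)
                    test[neg[pick, 0], neg[pick, 1]] = True
                train = np.ones((n, m), dtype=bool)
                train[held[:, 0], held[:, 1]] = False
                folds.append((train, test))
        else:
            axis_len = n if plan.scheme == "lncrna_rows" else m
            order = rng.permutation(axis_len)
            for chunk in np.array_split(order, plan.n_folds):
                test = np.zeros((n, m), dtype=bool)
                train = np.ones((n, m), dtype=bool)
                if plan.scheme == "lncrna_rows":
                    test[chunk, :] = True
                    train[chunk, :] = False
                else:
                    test[:, chunk] = True
                    train[:, chunk] = False
                folds.append((train, test))
        out.append(folds)
    return out


def _thresholded(scores, truth, threshold):
    pred = scores >= threshold
    tp = float(np.sum(pred & (truth == 1)))
    fp = float(np.sum(pred & (truth == 0)))
    tn = float(np.sum(~pred & (truth == 0)))
    fn = float(np.sum(~pred & (truth == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / max(tp + fp + tn + fn, 1.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, accuracy, f1


def compute_metrics(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold_policy: str = "minmax_half",
) -> MetricReport:
    """Ranking and thresholded metrics for one scored set of pairs.

    ``threshold_policy`` is ``"minmax_half"`` (rescale scores to [0, 1],
    threshold 0.5) or ``"best_f1"`` (the threshold maximizing F1).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in shape")
    if not np.isin(truth, (0.0, 1.0)).all():
        raise ValueError("truth must be binary")
    if truth.min() == truth.max():
        raise ValueError("AUC undefined: truth contains a single class")
    auc = float(roc_auc_score(truth, scores))
    aupr = float(average_precision_score(truth, scores))
    lo, hi = scores.min(), scores.max()
    rescaled = (scores - lo) / (hi - lo) if hi > lo else np.zeros_like(scores)
    if threshold_policy == "minmax_half":
        threshold = 0.5
    elif threshold_policy == "best_f1":
        candidates = np.unique(rescaled)
        threshold = max(candidates, key=lambda t: _thresholded(rescaled, truth, t)[3])
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    precision, recall, accuracy, f1 = _thresholded(rescaled, truth, threshold)
    return MetricReport(precision, recall, accuracy, f1, auc, aupr, float(threshold))


def cross_validate(
    Y: InteractionMatrix | np.ndarray,
    model_factory,
    plan: CVPlan,
    kernel_builder=None,
    threshold_policy: str = "minmax_half",
) -> MetricReport:
    """Run the CV protocol: refit (and optionally rebuild kernels) on each
    training matrix, score the test region, aggregate per-fold metrics.

    ``model_factory()`` returns an unfitted estimator with ``fit(Y,
    lncrna_sim=..., protein_sim=...)`` and ``predict()``;
    ``kernel_builder(train_Y)`` returns ``(lncrna_sim, protein_sim)``
    computed from the training matrix only (None disables graph terms).
    """
    values = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y, float)
    rows = []
    for rep, folds in enumerate(make_folds(values, plan)):
        for fold_idx, (train_mask, test_mask) in enumerate(folds):
            train_Y = values * train_mask
            if train_Y.sum() == 0:
                raise ValueError("training fold lost all positives")
            S_l, S_p = kernel_builder(train_Y) if kernel_builder else (None, None)
            model = model_factory()
            model.fit(train_Y, lncrna_sim=S_l, protein_sim=S_p)
            scores = model.predict()
            rep_metrics = compute_metrics(
                scores[test_mask], values[test_mask], threshold_policy
            )
            rows.append(
                {"repeat": rep, "fold": fold_idx, **rep_metrics.to_dict(),
                 "threshold": rep_metrics.threshold}
            )
    table = pd.DataFrame(rows)
    means = table[["precision", "recall", "accuracy", "f1", "auc", "aupr"]].mean()
    return MetricReport(
        float(means["precision"]),
        float(means["recall"]),
        float(means["accuracy"]),
        float(means["f1"]),
        float(means["auc"]),
        float(means["aupr"]),
        float(table["threshold"].mean()),
        per_fold=table,
    )


def rank_candidates(
    scores: np.ndarray,
    Y_known: InteractionMatrix,
    lncrna_id: str,
    top_n: int = 5,
) -> pd.DataFrame:
    """Top-scoring proteins for one lncRNA, flagged by whether the pair is
    already a known interaction; score ties broken by protein id."""
    if lncrna_id not in Y_known.lncrna_ids:
        raise KeyError(f"unknown lncRNA id {lncrna_id!r}")
    i = Y_known.lncrna_ids.index(lncrna_id)
    row = np.asarray(scores, dtype=float)[i]
    order = sorted(
        range(Y_known.m), key=lambda j: (-row[j], Y_known.protein_ids[j])
    )[:top_n]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "protein_id": [Y_known.protein_ids[j] for j in order],
            "score": [row[j] for j in order],
            "known": [bool(Y_known.values[i, j]) for j in order],
        }
    )


def grid_search(
    Y: InteractionMatrix | np.ndarray,
    model_factory,
    grid: dict[str, list],
    plan: CVPlan,
    kernel_builder=None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyper-parameter search by mean CV AUC.

    ``model_factory(**params)`` builds the estimator for one grid point.
    Returns the argmax parameter dict and the full results table (one row
    per combination); ties go to the first combination in grid order.
    """
    keys = list(grid)
    if not keys or any(len(grid[k]) == 0 for k in keys):
        raise ValueError("empty grid")
    rows = []
    best: tuple[float, dict] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        report = cross_validate(
            Y, lambda: model_factory(**params), plan, kernel_builder
        )
        rows.append({**params, "mean_auc": report.auc, "mean_aupr": report.aupr})
        if best is None or report.auc > best[0]:
            best = (report.auc, params)
        logger.info("grid point %s: AUC=%.4f", params, report.auc)
    assert best is not None
    return best[1], pd.DataFrame(rows)
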