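import numpy as np
import pandas as pd
import pytest

from wgrmf.evaluation import (
    CVPlan,
    compute_metrics,
    cross_validate,
    grid_search,
    make_folds,
    rank_candidates,
)
from wgrmf.factorization import WGRMF
from wgrmf.io import InteractionMatrix


def auc_pair_count_oracle(scores, truth):
    """Mann-Whitney statistic: concordant positive/negative pairs with half
    credit for ties."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_step_oracle(scores, truth):
    """Step integration of the precision-recall curve over distinct score
    thresholds (descending), ties grouped."""
    order = np.argsort(-scores, kind="stable")
    scores, truth = scores[order], truth[order]
    total_pos = truth.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += truth[i:j].sum()
        fp += (j - i) - truth[i:j].sum()
        recall = tp / total_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestMakeFolds:
    def test_even_partition_of_positives(self):
        values = np.zeros((5, 4))
        values.ravel()[:10] = 1
        plan = CVPlan(n_folds=5, repeats=1, seed=0)
        folds = make_folds(values, plan)[0]
        for train, test in folds:
            assert ((values == 1) & test).sum() == 2

    def test_determinism(self):
        values = (np.random.default_rng(3).random((6, 6)) < 0.4).astype(float)
        plan = CVPlan(n_folds=3, repeats=2, seed=11)
        a = make_folds(values, plan)
        b = make_folds(values, plan)
        for fa, fb in zip(a, b):
            for (tra, tea), (trb, teb) in zip(fa, fb):
                np.testing.assert_array_equal(tra, trb)
                np.testing.assert_array_equal(tea, teb)

    def test_test_positives_partition_all_positives(self):
        rng = np.random.default_rng(5)
        values = (rng.random((7, 5)) < 0.5).astype(float)
        plan = CVPlan(n_folds=4, repeats=1, seed=2)
        folds = make_folds(values, plan)[0]
        covered = np.zeros_like(values, dtype=int)
        for _, test in folds:
            covered += (test & (values == 1)).astype(int)
        np.testing.assert_array_equal(covered[values == 1], 1)

    def test_row_scheme_holds_out_whole_rows(self):
        values = np.ones((6, 3))
        plan = CVPlan(n_folds=3, repeats=1, scheme="lncrna_rows", seed=0)
        folds = make_folds(values, plan)[0]
        for train, test in folds:
            row_flags = test.any(axis=1)
            np.testing.assert_array_equal(test[row_flags], 1)
            assert (~train[row_flags]).all()

    def test_fewer_positives_than_folds(self):
        values = np.zeros((3, 3))
        values[0, 0] = 1
        with pytest.raises(ValueError, match="fewer positives"):
            make_folds(values, CVPlan(n_folds=5, repeats=1))


class TestComputeMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        truth = np.array([1, 1, 1, 0, 0, 0])
        rep = compute_metrics(scores, truth)
        assert rep.auc == 1.0 and rep.aupr == 1.0

    def test_reversed_scores_give_zero_auc(self):
        scores = np.array([0.1, 0.9])
        truth = np.array([1, 0])
        assert compute_metrics(scores, truth).auc == 0.0

    def test_auc_matches_pair_count_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, size=60).astype(float)  # many ties
        truth = (rng.random(60) < 0.3).astype(float)
        truth[0], truth[1] = 1, 0
        rep = compute_metrics(scores, truth)
        assert rep.auc == pytest.approx(auc_pair_count_oracle(scores, truth), abs=1e-12)

    def test_aupr_matches_step_integration_oracle(self, rng):
        scores = rng.integers(0, 7, size=80).astype(float)
        truth = (rng.random(80) < 0.4).astype(float)
        truth[0], truth[1] = 1, 0
        rep = compute_metrics(scores, truth)
        assert rep.aupr == pytest.approx(aupr_step_oracle(scores, truth), abs=1e-12)

    def test_f1_is_harmonic_mean(self, rng):
        scores = rng.random(50)
        truth = (rng.random(50) < 0.4).astype(float)
        truth[0], truth[1] = 1, 0
        rep = compute_metrics(scores, truth)
        if rep.precision + rep.recall > 0:
            expected = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestRankCandidates:
    @pytest.fixture
    def Y(self):
        return InteractionMatrix(
            ["l1", "l2"], ["pa", "pb", "pc"], np.array([[1.0, 0, 0], [0, 1, 0]])
        )

    def test_descending_rank(self, Y):
        scores = np.array([[0.9, 0.1, 0.5], [0.2, 0.3, 0.4]])
        table = rank_candidates(scores, Y, "l1", top_n=2)
        assert list(table["protein_id"]) == ["pa", "pc"]
        assert list(table["known"]) == [True, False]

    def test_tie_break_by_protein_id(self, Y):
        scores = np.full((2, 3), 0.5)
        table = rank_candidates(scores, Y, "l2", top_n=3)
        assert list(table["protein_id"]) == ["pa", "pb", "pc"]

    def test_agrees_with_independent_sort(self, Y, rng):
        scores = rng.random((2, 3))
        table = rank_candidates(scores, Y, "l1", top_n=3)
        expected = [Y.protein_ids[j] for j in np.argsort(-scores[0], kind="stable")]
        assert list(table["protein_id"]) == expected

    def test_unknown_id_rejected(self, Y):
        with pytest.raises(KeyError):
            rank_candidates(np.zeros((2, 3)), Y, "nope")


@pytest.fixture
def cv_setup(rng):
    values = (rng.random((12, 8)) < 0.35).astype(float)
    values[0, 0] = 1.0
    plan = CVPlan(n_folds=3, repeats=1, seed=4)
    return values, plan


class TestCrossValidate:
    def test_mean_equals_reaggregated_per_fold(self, cv_setup):
        values, plan = cv_setup
        report = cross_validate(values, lambda: WGRMF(n_components=3), plan)
        assert report.auc == pytest.approx(report.per_fold["auc"].mean())
        assert report.aupr == pytest.approx(report.per_fold["aupr"].mean())
        assert len(report.per_fold) == 3

    def test_metrics_within_unit_interval(self, cv_setup):
        values, plan = cv_setup
        report = cross_validate(values, lambda: WGRMF(n_components=3), plan)
        for v in report.to_dict().values():
            assert 0.0 <= v <= 1.0


class TestGridSearch:
    def test_single_point_grid(self, cv_setup):
        values, plan = cv_setup
        best, table = grid_search(
            values, lambda **p: WGRMF(n_components=3, **p),
            {"lambda_f": [0.5]}, plan,
        )
        assert best == {"lambda_f": 0.5} and len(table) == 1

    def test_table_covers_grid_product(self, cv_setup):
        values, plan = cv_setup
        _, table = grid_search(
            values, lambda **p: WGRMF(n_components=2, **p),
            {"lambda_f": [0.25, 0.5], "unknown_weight": [0.1, 0.5, 1.0]}, plan,
        )
        assert len(table) == 6

    def test_dominating_configuration_wins(self, rng):
        """On a planted low-rank matrix, a sensible rank beats a crippled
        rank-1 + huge-ridge configuration, and grid search returns it."""
        A = rng.standard_normal((14, 3))
        B = rng.standard_normal((10, 3))
        aff = A @ B.T
        values = (aff > np.quantile(aff, 0.75)).astype(float)
        plan = CVPlan(n_folds=3, repeats=1, seed=9)
        grid = {"n_components": [1, 6], "lambda_f": [0.5, 500.0]}
        best, table = grid_search(
            values, lambda **p: WGRMF(unknown_weight=0.1, **p), plan=plan,
            grid=grid,
        )
        direct = table.loc[table["mean_auc"].idxmax()]
        assert best["n_components"] == direct["n_components"]
        assert best["lambda_f"] == direct["lambda_f"]
        assert best["lambda_f"] != 500.0

    def test_empty_grid_rejected(self, cv_setup):
        values, plan = cv_setup
        with pytest.raises(ValueError, match="empty grid"):
            grid_search(values, lambda **p: WGRMF(**p), {}, plan)
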