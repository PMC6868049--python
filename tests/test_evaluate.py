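"""LOOCV classification, metric identities and curve computation."""

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from rfradiomics.evaluate import (
    SVMConfig,
    binary_metrics,
    delong_ci,
    loocv_predict,
    roc_prc_dca,
    sweep_k,
    trapezoid_auc,
)

from oracles import mann_whitney_auc


def separable_toy(rng, n=16, gap=20.0):
    y = np.array([1, 0] * (n // 2))
    X = rng.standard_normal((n, 2)) + gap * y[:, None]
    return X, y


class TestLOOCV:
    def test_separable_data_perfect_accuracy(self, rng):
        X, y = separable_toy(rng)
        _, preds = loocv_predict(X, y)
        assert binary_metrics(y, preds)["accuracy"] == 1.0

    def test_shuffled_labels_null_auc(self, rng):
        X, _ = separable_toy(rng, n=20, gap=0.0)
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.permutation([1, 0] * 10)
            scores, _ = loocv_predict(X, y)
            aucs.append(trapezoid_auc(scores, y))
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_duplicated_feature_columns_change_nothing(self, rng):
        X, y = separable_toy(rng, gap=2.0)
        s1, p1 = loocv_predict(X, y)
        s2, p2 = loocv_predict(np.hstack([X, X]), y)
        np.testing.assert_allclose(s1, s2, atol=1e-8)
        assert np.array_equal(p1, p2)

    def test_held_out_sample_never_trains_its_fold(self, rng):
        """Replacing sample i by garbage must not change the model it is
        scored by: that model is refit here from the other N-1 alone."""
        X, y = separable_toy(rng, gap=2.0)
        i = 3
        X2 = X.copy()
        X2[i] = 1e3 * rng.standard_normal(2)
        scores2, _ = loocv_predict(X2, y)
        train = np.arange(len(y)) != i
        scaler = StandardScaler().fit(X2[train])
        clf = SVMConfig().make().fit(scaler.transform(X2[train]), y[train])
        expected = clf.decision_function(scaler.transform(X2[i : i + 1]))[0]
        assert scores2[i] == pytest.approx(expected, abs=1e-10)

    def test_tiny_or_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_predict(rng.standard_normal((3, 2)), np.array([1, 0, 1]))
        with pytest.raises(ValueError):
            loocv_predict(rng.standard_normal((6, 2)), np.ones(6))


class TestCurves:
    def test_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        out = roc_prc_dca(np.array([2.0, 1.5, -1.0, -2.0]), y)
        assert out["auc"] == pytest.approx(1.0)
        recalls = out["prc"][:, 0]
        precisions = out["prc"][:, 1]
        # at every attainable recall there is a threshold with precision 1
        for r in np.unique(recalls[recalls > 0]):
            assert precisions[recalls == r].max() == 1.0

    def test_hand_counted_auc(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        y = np.array([1, 0, 1, 0])
        out = roc_prc_dca(scores, y)
        assert out["auc"] == pytest.approx(0.75)   # 3 of 4 concordant pairs

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.standard_normal(n), 1)  # force some ties
            assert trapezoid_auc(scores, y) == pytest.approx(
                mann_whitney_auc(scores, y), abs=1e-12
            )

    def test_net_benefit_zero_when_nobody_predicted(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        # heavily overlapping scores: fitted probabilities stay moderate,
        # so at the top of the threshold grid nobody is predicted positive
        scores = np.array([0.10, 0.00, 0.20, 0.15, 0.05, 0.12])
        out = roc_prc_dca(scores, y)
        pt, nb = out["dca"][-1]  # highest threshold: nobody predicted positive
        assert nb == 0.0

    def test_constant_scores_flagged_degenerate(self):
        y = np.array([1, 0, 1, 0])
        out = roc_prc_dca(np.zeros(4), y)
        assert out["degenerate"]
        assert out["auc_delong"] == pytest.approx(0.5)

    def test_delong_ci_orders_and_covers(self, rng):
        y = np.array([1] * 10 + [0] * 10)
        scores = rng.standard_normal(20) + 1.5 * y
        auc, (lo, hi), degenerate = delong_ci(scores, y)
        assert not degenerate
        assert 0.0 <= lo <= auc <= hi <= 1.0


class TestSweepK:
    def test_metrics_recomputable_from_confusion(self, rng):
        X, y = separable_toy(rng, n=12, gap=1.0)
        res = sweep_k(X, y, k_max=2)
        assert len(res.per_k) == 2
        m = binary_metrics(y, res.predictions)
        row = res.best_row
        assert row["accuracy"] == pytest.approx(m["accuracy"])
        assert row["sensitivity"] == pytest.approx(m["sensitivity"])
        assert row["specificity"] == pytest.approx(m["specificity"])

    def test_k_max_clipped_and_single_k(self, rng):
        X, y = separable_toy(rng, n=12)
        res = sweep_k(X[:, :1], y, k_max=5)
        assert len(res.per_k) == 1 and res.best_k == 1

    def test_best_k_prefers_smaller_on_ties(self, rng):
        X, y = separable_toy(rng, n=12, gap=30.0)  # every k is perfect
        res = sweep_k(X, y, k_max=2)
        assert res.best_k == 1
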