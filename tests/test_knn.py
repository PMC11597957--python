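"""KNN monitor: oracle equivalence, tie-breaking, invariances, reports."""

import numpy as np
import pytest

from pawmoco import (KnnConfig, MemoryBank, WeightedKNNClassifier,
                     chance_accuracy, classification_report, knn_predict)


def _unit(rows):
    rows = np.asarray(rows, dtype=np.float64)
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def brute_force_knn(queries, bank_feats, bank_labels, k, temperature, n_classes):
    """Exhaustive reference: full sort with (similarity desc, index asc) keys,
    explicit per-class weight sums, argmax with smallest-index tie-break."""
    preds = []
    for q in queries:
        sims = [(float(q @ f), i) for i, f in enumerate(bank_feats)]
        sims.sort(key=lambda t: (-t[0], t[1]))
        top = sims[:min(k, len(sims))]
        scores = [0.0] * n_classes
        for s, i in top:
            scores[bank_labels[i]] += np.exp(s / temperature)
        best = max(range(n_classes), key=lambda c: (scores[c], -c))
        preds.append(best)
    return np.array(preds)


class TestKnnPredict:
    def test_self_retrieval_with_k1(self):
        bank = MemoryBank(features=_unit([[1, 0], [0, 1]]), labels=[0, 1])
        pred, scores = knn_predict(_unit([[0, 1]]), bank,
                                   KnnConfig(k=1, temperature=0.1, num_classes=2))
        assert pred[0] == 1
        assert scores[0, 1] == pytest.approx(1.0)

    def test_four_vector_weighted_vote(self):
        feats = _unit([[1, 0], [0.9, np.sqrt(0.19)], [0, 1], [-1, 0]])
        bank = MemoryBank(features=feats, labels=[0, 0, 1, 1])
        pred, scores = knn_predict(_unit([[1, 0]]), bank,
                                   KnnConfig(k=3, temperature=0.1, num_classes=2))
        assert pred[0] == 0
        # oracle: weights e^10, e^9, e^0 -> class 0 dominates overwhelmingly
        w = np.exp(np.array([1.0, 0.9, 0.0]) / 0.1)
        assert scores[0, 0] == pytest.approx((w[0] + w[1]) / w.sum(), rel=1e-9)

    def test_single_class_bank_always_wins(self, rng):
        feats = _unit(rng.normal(size=(10, 4)))
        bank = MemoryBank(features=feats, labels=[2] * 10)
        queries = _unit(rng.normal(size=(6, 4)))
        for k, t in [(1, 0.1), (5, 1.0), (10, 0.01)]:
            pred, _ = knn_predict(queries, bank, KnnConfig(k, t, num_classes=4))
            assert (pred == 2).all()

    def test_matches_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            d = int(rng.integers(2, 9))
            k = int(rng.integers(1, n + 1))
            c = int(rng.integers(2, 6))
            t = float(rng.uniform(0.05, 1.0))
            feats = _unit(rng.normal(size=(n, d)))
            labels = rng.integers(0, c, size=n)
            m = min(c, n)
            labels[:m] = np.arange(m)              # spread classes across rows
            queries = _unit(rng.normal(size=(4, d)))
            bank = MemoryBank(features=feats, labels=labels)
            pred, _ = knn_predict(queries, bank, KnnConfig(k, t, c))
            expected = brute_force_knn(queries, feats, labels, k, t, c)
            assert np.array_equal(pred, expected)

    def test_constant_features_resolve_by_index_tie_break(self):
        # all similarities equal -> top-k are the first k bank rows
        feats = np.tile(_unit([[1.0, 0.0]]), (6, 1))
        labels = np.array([1, 1, 0, 2, 2, 2])
        bank = MemoryBank(features=feats, labels=labels)
        pred, _ = knn_predict(feats[:1], bank, KnnConfig(k=3, temperature=0.1,
                                                         num_classes=3))
        assert pred[0] == 1            # rows 0,1,2 vote {1:2, 0:1}
        pred_all, _ = knn_predict(feats[:1], bank,
                                  KnnConfig(k=6, temperature=0.1, num_classes=3))
        assert pred_all[0] == 2        # full bank: modal class

    def test_permutation_invariance_without_ties(self):
        rng = np.random.default_rng(7)
        feats = _unit(rng.normal(size=(20, 5)))
        labels = rng.integers(0, 3, size=20)
        labels[:3] = [0, 1, 2]
        queries = _unit(rng.normal(size=(5, 5)))
        cfg = KnnConfig(k=7, temperature=0.2, num_classes=3)
        base, _ = knn_predict(queries, MemoryBank(feats, labels), cfg)
        perm = rng.permutation(20)
        permuted, _ = knn_predict(queries, MemoryBank(feats[perm], labels[perm]),
                                  cfg)
        assert np.array_equal(base, permuted)

    def test_invariance_under_common_orthogonal_rotation(self):
        rng = np.random.default_rng(8)
        feats = _unit(rng.normal(size=(30, 6)))
        labels = rng.integers(0, 3, size=30)
        labels[:3] = [0, 1, 2]
        queries = _unit(rng.normal(size=(8, 6)))
        rot, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        cfg = KnnConfig(k=9, temperature=0.1, num_classes=3)
        base, _ = knn_predict(queries, MemoryBank(feats, labels), cfg)
        rotated, _ = knn_predict(queries @ rot, MemoryBank(feats @ rot, labels),
                                 cfg)
        assert np.array_equal(base, rotated)

    def test_chance_level_for_random_features_and_shuffled_labels(self):
        rng = np.random.default_rng(9)
        n_train, n_test, c = 700, 700, 7
        feats = _unit(rng.normal(size=(n_train, 16)))
        labels = np.repeat(np.arange(c), n_train // c)
        rng.shuffle(labels)
        queries = _unit(rng.normal(size=(n_test, 16)))
        true = np.repeat(np.arange(c), n_test // c)
        pred, _ = knn_predict(queries, MemoryBank(feats, labels),
                              KnnConfig(k=200, temperature=0.1, num_classes=c))
        acc = (pred == true).mean() * 100
        p = 1 / c
        half_width = 2.576 * np.sqrt(p * (1 - p) / n_test) * 100
        assert abs(acc - chance_accuracy(c)) < half_width

    def test_errors(self):
        bank = MemoryBank(features=_unit([[1, 0]]), labels=[0])
        with pytest.raises(ValueError):
            knn_predict(np.ones((2, 3)), bank, KnnConfig(1, 0.1, 2))
        with pytest.raises(ValueError):
            MemoryBank(features=np.zeros((0, 2)), labels=[])


class TestWeightedKNNClassifierEstimator:
    def test_sklearn_interface_round_trip(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 5))
        y = np.array(["cat", "dog"] * 20)
        clf = WeightedKNNClassifier(k=5, temperature=0.5)
        assert clf.get_params() == {"k": 5, "temperature": 0.5}
        clf.fit(X, y)
        pred = clf.predict(X[:10])
        assert set(pred) <= {"cat", "dog"}
        proba = clf.predict_proba(X[:10])
        assert proba.shape == (10, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_perfect_features_give_perfect_accuracy(self):
        X = np.eye(4).repeat(5, axis=0)
        y = np.arange(4).repeat(5)
        clf = WeightedKNNClassifier(k=3, temperature=0.1).fit(X, y)
        assert (clf.predict(X) == y).all()


class TestClassificationReport:
    def test_perfect_predictions(self):
        rep = classification_report([0, 1, 2, 0], [0, 1, 2, 0], ["a", "b", "c"])
        assert rep.accuracy == 100.0
        per_class = rep.frame[rep.frame["Emotion"] != "macro avg"]
        assert (per_class[["Precision", "Recall", "F1-Score"]] == 1.0).all().all()

    def test_toy_confusion_matrix_oracle(self):
        # labels [A,A,B,B], preds [A,B,B,B]
        rep = classification_report([0, 1, 1, 1], [0, 0, 1, 1], ["A", "B"])
        row_a = rep.frame.set_index("Emotion").loc["A"]
        row_b = rep.frame.set_index("Emotion").loc["B"]
        assert row_b["Precision"] == pytest.approx(2 / 3)
        assert row_a["Recall"] == pytest.approx(1 / 2)
        assert rep.accuracy == pytest.approx(75.0)
        macro = rep.frame.set_index("Emotion").loc["macro avg"]
        assert macro["Precision"] == pytest.approx((1.0 + 2 / 3) / 2)

    def test_report_layout_matches_emotion_table_structure(self):
        rep = classification_report([0, 1], [0, 1], ["Caring", "Exploring"])
        assert list(rep.frame.columns) == ["Emotion", "Precision", "Recall",
                                           "F1-Score", "Support"]
        assert rep.frame["Emotion"].tolist() == ["Caring", "Exploring",
                                                 "macro avg"]

    def test_errors(self):
        with pytest.raises(ValueError):
            classification_report([0], [0, 1], ["a", "b"])
        with pytest.raises(ValueError):
            classification_report([], [], ["a"])
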