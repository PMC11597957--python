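"""Temperature-weighted K-nearest-neighbor classification of embeddings.

The monitor classifies a query embedding by cosine similarity against a
memory bank of training embeddings: the top ``k`` neighbors vote with weights
``exp(similarity / temperature)`` on their one-hot labels, and the class with
the largest weighted sum wins.  Ties — equal similarities during neighbor
selection, equal class scores at the argmax — break toward the lower bank
index and the smaller class index respectively, which keeps the monitor fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .data import IMAGENET_MEAN, IMAGENET_STD, eval_batch
from .datasets import LabeledImageSet


@dataclass
class KnnConfig:
    k: int = 200
    temperature: float = 0.1
    num_classes: int = 7

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class MemoryBank:
    features: np.ndarray   # (N, d), unit rows
    labels: np.ndarray     # (N,)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if len(self.features) == 0:
            raise ValueError("memory bank must be non-empty")


def knn_predict(queries: np.ndarray, bank: MemoryBank,
                cfg: KnnConfig) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and normalized class scores for unit-norm queries.

    Returns ``(labels, scores)`` with ``scores`` of shape
    (n_queries, num_classes), each row summing to 1.
    """
    queries = np.asarray(queries, dtype=np.float64)
    if queries.ndim != 2 or queries.shape[1] != bank.features.shape[1]:
        raise ValueError("query/bank dimension mismatch")
    n_bank = len(bank.features)
    k = min(cfg.k, n_bank)
    sims = queries @ bank.features.T
    # stable sort on -sim: equal similarities keep ascending bank index
    order = np.argsort(-sims, axis=1, kind="stable")[:, :k]
    top_sims = np.take_along_axis(sims, order, axis=1)
    top_labels = bank.labels[order]
    weights = np.exp(top_sims / cfg.temperature)
    scores = np.zeros((len(queries), cfg.num_classes), dtype=np.float64)
    rows = np.repeat(np.arange(len(queries)), k)
    np.add.at(scores, (rows, top_labels.ravel()), weights.ravel())
    predictions = scores.argmax(axis=1)           # ties -> smallest class index
    scores = scores / scores.sum(axis=1, keepdims=True)
    return predictions, scores


class WeightedKNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around :func:`knn_predict`.

    ``fit`` stores L2-normalized training features as the memory bank;
    ``predict`` votes with temperature-scaled cosine similarities.
    """

    def __init__(self, k: int = 200, temperature: float = 0.1):
        self.k = k
        self.temperature = temperature

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, encoded = np.unique(y, return_inverse=True)
        norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        self.bank_ = MemoryBank(features=X / norms, labels=encoded)
        return self

    def _cfg(self) -> KnnConfig:
        return KnnConfig(k=self.k, temperature=self.temperature,
                         num_classes=len(self.classes_))

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        pred, _ = knn_predict(X / norms, self.bank_, self._cfg())
        return self.classes_[pred]

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        _, scores = knn_predict(X / norms, self.bank_, self._cfg())
        return scores


def embed_images(encoder: nn.Module, images: list[np.ndarray], image_size: int,
                 mean=IMAGENET_MEAN, std=IMAGENET_STD,
                 batch_size: int = 128) -> np.ndarray:
    """Eval-mode features of a list of uint8 images (deterministic)."""
    was_training = encoder.training
    encoder.eval()
    try:
        chunks = []
        with nn.no_grad():
            for start in range(0, len(images), batch_size):
                batch = eval_batch(images[start:start + batch_size], image_size,
                                   mean, std)
                chunks.append(encoder.forward(batch))
        return np.concatenate(chunks, axis=0)
    finally:
        encoder.train(was_training)


def evaluate_knn_accuracy(encoder: nn.Module, dataset: LabeledImageSet,
                          cfg: KnnConfig | None = None, image_size: int = 96,
                          mean=IMAGENET_MEAN, std=IMAGENET_STD) -> float:
    """Percent of test images whose KNN-voted label matches the truth.

    The memory bank holds eval-transformed train-split features from the
    (query) encoder; queries are the test split.
    """
    cfg = cfg if cfg is not None else KnnConfig(num_classes=dataset.n_classes)
    train_idx, test_idx = dataset.train_indices, dataset.test_indices
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("dataset needs non-empty train and test splits")
    bank_feats = embed_images(encoder, dataset.subset_images(train_idx), image_size,
                              mean, std)
    query_feats = embed_images(encoder, dataset.subset_images(test_idx), image_size,
                               mean, std)
    bank = MemoryBank(features=bank_feats, labels=dataset.labels[train_idx])
    pred, _ = knn_predict(query_feats, bank,
                          KnnConfig(cfg.k, cfg.temperature, dataset.n_classes))
    return float((pred == dataset.labels[test_idx]).mean() * 100.0)


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1 plus accuracy and macro averages."""

    frame: pd.DataFrame          # rows: one per class + "macro avg"
    accuracy: float              # percent

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def classification_report(predicted: np.ndarray, true: np.ndarray,
                          class_names: list[str]) -> ClassificationReport:
    """Confusion-matrix summary mirroring the usual emotion-report layout.

    Columns: Emotion, Precision, Recall, F1-Score, Support; a final
    ``macro avg`` row carries the unweighted class means.  Undefined ratios
    (no predictions / no support for a class) are reported as 0.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if len(predicted) != len(true):
        raise ValueError("prediction and truth vectors must have equal length")
    if len(true) == 0:
        raise ValueError("empty input")
    labels = np.arange(len(class_names))
    prec, rec, f1, support = precision_recall_fscore_support(
        true, predicted, labels=labels, zero_division=0)
    rows = [{"Emotion": name, "Precision": p, "Recall": r, "F1-Score": f,
             "Support": int(s)}
            for name, p, r, f, s in zip(class_names, prec, rec, f1, support)]
    rows.append({"Emotion": "macro avg", "Precision": prec.mean(),
                 "Recall": rec.mean(), "F1-Score": f1.mean(),
                 "Support": int(support.sum())})
    accuracy = float((predicted == true).mean() * 100.0)
    return ClassificationReport(frame=pd.DataFrame(rows), accuracy=accuracy)
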