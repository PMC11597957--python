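"""Supervised transfer-learning benchmark: ResNet classifier + cross-entropy.

The reference configuration is a ResNet50 whose final fully connected layer
is replaced by a ``num_classes`` output, trained with Adam (lr 1e-3) and
cross-entropy for 20 epochs on an 80/20 stratified split, with rotation/flip
augmentation and ImageNet normalization.  Pretrained backbone weights can be
loaded from a local ``.npz`` state file when available; by default training
starts from seeded random initialization so runs are self-contained offline.
Smaller architectures/widths support desk-scale CPU experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .data import IMAGENET_MEAN, IMAGENET_STD, eval_batch, normalize_chw
from .datasets import LabeledImageSet, stratified_split
from .knn import classification_report


@dataclass
class SupervisedConfig:
    arch: str = "resnet50"
    width: int = 64
    pretrained: bool = False
    weights_path: str | None = None    # local .npz state dict for the backbone
    lr: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    rotation_degrees: float = 10.0
    p_hflip: float = 0.5
    resize: int = 224
    mean: tuple = IMAGENET_MEAN
    std: tuple = IMAGENET_STD
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.resize) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size, resize and lr must be positive")
        if self.pretrained and not self.weights_path:
            raise ValueError(
                "pretrained=True requires weights_path (no weights are bundled)")


def _augment_supervised(img: np.ndarray, cfg: SupervisedConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Train-time transform: rotate, flip, resize, center crop, normalize."""
    pil = Image.fromarray(img)
    angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
    pil = pil.rotate(angle, resample=Image.BILINEAR)
    if rng.random() < cfg.p_hflip:
        pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
    pil = pil.resize((cfg.resize, cfg.resize), Image.BILINEAR)
    # center crop at equal size is the identity; kept explicit for fidelity
    w, h = pil.size
    left, top = (w - cfg.resize) // 2, (h - cfg.resize) // 2
    pil = pil.crop((left, top, left + cfg.resize, top + cfg.resize))
    return normalize_chw(pil, cfg.mean, cfg.std)


def build_classifier(cfg: SupervisedConfig, num_classes: int) -> nn.ResNet:
    """ResNet with its head replaced by a ``num_classes``-way linear output."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
    model = nn.ResNet(cfg.arch, width=cfg.width, feature_dim=num_classes,
                      num_splits=1, cifar_stem=cfg.resize < 64,
                      l2_normalize=False, rng=rng)
    if cfg.pretrained and cfg.weights_path:
        state = dict(np.load(cfg.weights_path))
        own = model.state_dict()
        # load everything except the (freshly shaped) classification head
        loadable = {k: v for k, v in state.items()
                    if k in own and own[k].shape == v.shape and not k.startswith("fc.")}
        own.update(loadable)
        model.load_state_dict(own)
    return model


def train_supervised(dataset: LabeledImageSet, cfg: SupervisedConfig,
                     ) -> tuple[nn.ResNet, pd.DataFrame]:
    """Adam + cross-entropy training; returns (best-epoch model, history).

    History columns: epoch, train_loss, test_accuracy_pct.  The returned
    model carries the parameters of the best held-out-accuracy epoch.
    """
    train_idx, test_idx = dataset.train_indices, dataset.test_indices
    if len(train_idx) == 0:
        raise ValueError("empty train split")
    if dataset.n_classes < 2:
        raise ValueError("need at least two classes")
    model = build_classifier(cfg, dataset.n_classes)
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 59]))
    train_images = dataset.subset_images(train_idx)
    train_labels = dataset.labels[train_idx]

    best_acc, best_state = -1.0, None
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_images))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = np.stack([_augment_supervised(train_images[i], cfg, rng)
                          for i in idx])
            logits = model.forward(x)
            loss, dlogits = nn.softmax_cross_entropy(logits, train_labels[idx])
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        acc = np.nan
        if len(test_idx):
            acc = evaluate_accuracy(model, dataset, cfg)
            if acc > best_acc:
                best_acc, best_state = acc, model.state_dict()
        history.append({"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                        "test_accuracy_pct": acc})
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def predict_labels(model: nn.ResNet, images: list[np.ndarray],
                   cfg: SupervisedConfig, batch_size: int = 64) -> np.ndarray:
    model.eval()
    preds = []
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            x = eval_batch(images[start:start + batch_size], cfg.resize,
                           cfg.mean, cfg.std)
            preds.append(model.forward(x).argmax(axis=1))
    return np.concatenate(preds)


def evaluate_accuracy(model: nn.ResNet, dataset: LabeledImageSet,
                      cfg: SupervisedConfig) -> float:
    test_idx = dataset.test_indices
    pred = predict_labels(model, dataset.subset_images(test_idx), cfg)
    return float((pred == dataset.labels[test_idx]).mean() * 100.0)


def compare_supervised_vs_unsupervised(dataset: LabeledImageSet,
                                       sup_cfg: SupervisedConfig,
                                       enc_cfg, moco_cfg) -> pd.DataFrame:
    """Accuracy table (overall + per-class recall) for both training routes.

    Rows: the supervised classifier and the MoCo encoder + KNN monitor,
    evaluated on the same held-out split.  Columns: method, overall
    accuracy (percent), then one per-class recall column per emotion.
    """
    from .knn import KnnConfig, MemoryBank, embed_images, knn_predict
    from .moco import train_moco

    test_idx = dataset.test_indices
    true = dataset.labels[test_idx]

    sup_model, _ = train_supervised(dataset, sup_cfg)
    sup_pred = predict_labels(sup_model, dataset.subset_images(test_idx), sup_cfg)

    encoder, _ = train_moco(dataset, enc_cfg, moco_cfg, monitor=False)
    bank = MemoryBank(
        features=embed_images(encoder, dataset.subset_images(dataset.train_indices),
                              moco_cfg.image_resolution),
        labels=dataset.labels[dataset.train_indices])
    moco_pred, _ = knn_predict(
        embed_images(encoder, dataset.subset_images(test_idx),
                     moco_cfg.image_resolution),
        bank, KnnConfig(moco_cfg.knn_k, moco_cfg.knn_temperature,
                        dataset.n_classes))

    rows = []
    for method, pred in (("supervised", sup_pred), ("moco_knn", moco_pred)):
        row = {"method": method,
               "overall_accuracy_pct": float((pred == true).mean() * 100.0)}
        for c, name in enumerate(dataset.class_names):
            mask = true == c
            row[f"recall_{name}_pct"] = float((pred[mask] == c).mean() * 100.0) \
                if mask.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class SupervisedImageClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style image classifier over the numpy ResNet backbones."""

    def __init__(self, arch: str = "resnet50", width: int = 64,
                 lr: float = 0.001, epochs: int = 20, batch_size: int = 32,
                 resize: int = 224, test_fraction: float = 0.2,
                 random_state: int = 0):
        self.arch = arch
        self.width = width
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.resize = resize
        self.test_fraction = test_fraction
        self.random_state = random_state

    def _cfg(self) -> SupervisedConfig:
        return SupervisedConfig(arch=self.arch, width=self.width, lr=self.lr,
                                epochs=self.epochs, batch_size=self.batch_size,
                                resize=self.resize, seed=self.random_state)

    def fit(self, X, y):
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        y = np.asarray(y)
        self.classes_, encoded = np.unique(y, return_inverse=True)
        mask = stratified_split(encoded, self.test_fraction, seed=self.random_state)
        dataset = LabeledImageSet(images=images, labels=encoded,
                                  class_names=[str(c) for c in self.classes_],
                                  is_test=mask)
        self.model_, self.history_ = train_supervised(dataset, self._cfg())
        return self

    def predict(self, X):
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        return self.classes_[predict_labels(self.model_, images, self._cfg())]

    def report(self, X, y):
        pred = self.predict(X)
        return classification_report(pred, np.asarray(y),
                                     [str(c) for c in self.classes_])
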