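"""Momentum contrast: queue of negatives, EMA key encoder, contrastive loss.

Two encoders of identical architecture process the two augmented views of
each image: the query encoder is trained by SGD, the key encoder is an
exponential moving average of the query encoder's weights (momentum ``m``,
paper setting 0.99) and receives no gradients.  Keys from past batches are
held in a FIFO queue of unit-norm feature vectors and serve as negatives, so
the number of negatives is decoupled from the batch size.  The per-example
loss is a temperature-scaled (1 + K)-way softmax cross-entropy with the
positive key as the target:

    L_q = -ln[ exp(q . k+ / tau) / ( exp(q . k+ / tau)
               + sum_i exp(q . queue_i / tau) ) ]

averaged over the batch.  The learning rate follows cosine annealing over the
configured epoch budget, and a temperature-weighted KNN monitor tracks test
accuracy after every epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .data import AugmentationConfig, two_view_batches
from .datasets import LabeledImageSet, stratified_split
from .encoders import EncoderConfig, build_encoder
from .knn import KnnConfig, embed_images, evaluate_knn_accuracy
from .simclr import ntxent_inbatch_loss


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def contrastive_loss(q: np.ndarray, k_pos: np.ndarray, queue: np.ndarray,
                     temperature: float,
                     return_grad: bool = False):
    """Mean queue-denominator contrastive loss; optionally d(loss)/dq.

    Equals the cross-entropy of a (1 + K)-way softmax over
    ``[q.k+, q.queue_1, ..., q.queue_K] / temperature`` with target index 0.
    Gradients flow into ``q`` only (keys and queue entries are detached).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    q = np.asarray(q, dtype=np.float64)
    k_pos = np.asarray(k_pos, dtype=np.float64)
    queue = np.asarray(queue, dtype=np.float64)
    if q.shape != k_pos.shape:
        raise ValueError("q and k_pos shape mismatch")
    if queue.size and queue.shape[1] != q.shape[1]:
        raise ValueError("queue dimension mismatch")
    batch = q.shape[0]
    l_pos = np.sum(q * k_pos, axis=1, keepdims=True)
    l_neg = q @ queue.T if queue.size else np.zeros((batch, 0))
    logits = np.concatenate([l_pos, l_neg], axis=1) / temperature
    loss, dlogits = nn.softmax_cross_entropy(logits, np.zeros(batch, dtype=np.int64))
    if not return_grad:
        return loss
    dlogits = dlogits.astype(np.float64) / temperature
    dq = dlogits[:, :1] * k_pos
    if queue.size:
        dq = dq + dlogits[:, 1:] @ queue
    return loss, dq.astype(np.float32)


# ---------------------------------------------------------------------------
# EMA and queue
# ---------------------------------------------------------------------------

def ema_update(query_encoder: nn.Module, key_encoder: nn.Module, m: float) -> None:
    """theta_k <- m * theta_k + (1 - m) * theta_q, in place, gradient-free."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("momentum m must lie in [0, 1]")
    q_params = dict(query_encoder.named_parameters())
    k_params = dict(key_encoder.named_parameters())
    if q_params.keys() != k_params.keys():
        raise ValueError("query/key encoders have different parameter sets")
    for name, qp in q_params.items():
        kp = k_params[name]
        if kp.data.shape != qp.data.shape:
            raise ValueError(f"shape mismatch at {name}")
        kp.data *= m
        kp.data += (1.0 - m) * qp.data


class MoCoQueue:
    """FIFO ring buffer of unit-norm key features."""

    def __init__(self, queue_size: int, feature_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        feats = rng.normal(size=(queue_size, feature_dim))
        feats /= np.linalg.norm(feats, axis=1, keepdims=True)
        self.features = feats.astype(np.float32)
        self.ptr = 0

    @property
    def size(self) -> int:
        return len(self.features)

    def enqueue(self, new_keys: np.ndarray) -> None:
        """Overwrite rows starting at ptr (wrapping); advance ptr modulo size."""
        new_keys = np.asarray(new_keys, dtype=np.float32)
        b = len(new_keys)
        if b > self.size:
            raise ValueError("batch larger than queue")
        end = self.ptr + b
        if end <= self.size:
            self.features[self.ptr:end] = new_keys
        else:
            first = self.size - self.ptr
            self.features[self.ptr:] = new_keys[:first]
            self.features[:end - self.size] = new_keys[first:]
        self.ptr = end % self.size


def enqueue_dequeue(queue: MoCoQueue, new_keys: np.ndarray) -> MoCoQueue:
    """Functional wrapper: FIFO replacement with pointer wrap, in place."""
    queue.enqueue(new_keys)
    return queue


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class MoCoTrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.3
    momentum: float = 0.99            # EMA momentum m
    temperature: float = 0.1          # contrastive temperature tau
    epochs: int = 200
    queue_size: int = 4096
    knn_k: int = 200
    knn_temperature: float = 0.1
    image_resolution: int = 96
    seed: int = 0
    sgd_momentum: float = 0.9
    weight_decay: float = 1e-4
    crop_scale: tuple[float, float] = (0.2, 1.0)
    loss: str = "queue"               # "queue" (default) or "inbatch" NT-Xent

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.queue_size, self.knn_k,
               self.image_resolution) < 1:
            raise ValueError("all size/count fields must be positive")
        if self.temperature <= 0 or self.knn_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("EMA momentum must lie in [0, 1]")
        if self.loss not in ("queue", "inbatch"):
            raise ValueError("loss must be 'queue' or 'inbatch'")


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


def train_moco(dataset: LabeledImageSet, enc_config: EncoderConfig,
               cfg: MoCoTrainConfig,
               monitor: bool = True) -> tuple[nn.ResNet, pd.DataFrame]:
    """Run the momentum-contrast loop; returns (query encoder, history).

    History has one row per epoch with columns (epoch, train_loss,
    knn_accuracy_pct); the accuracy column is NaN when ``monitor`` is off.
    """
    train_idx = dataset.train_indices
    if len(train_idx) == 0:
        raise ValueError("empty train split")
    if cfg.batch_size % enc_config.num_bn_splits != 0:
        raise ValueError("batch_size must be divisible by num_bn_splits")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    enc_q = build_encoder(enc_config, np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 23])))
    enc_k = copy.deepcopy(enc_q)       # key encoder starts as an exact copy
    queue = MoCoQueue(cfg.queue_size, enc_config.feature_dim,
                      np.random.default_rng(np.random.SeedSequence([cfg.seed, 29])))
    optimizer = nn.SGD(enc_q.parameters(), cfg.learning_rate,
                       momentum=cfg.sgd_momentum, weight_decay=cfg.weight_decay)
    aug = AugmentationConfig(crop_size=cfg.image_resolution,
                             crop_scale=cfg.crop_scale)
    knn_cfg = KnnConfig(k=cfg.knn_k, temperature=cfg.knn_temperature,
                        num_classes=dataset.n_classes)
    train_images = dataset.subset_images(train_idx)

    # Warm-fill the queue with key-encoder features of augmented training
    # images so the first epoch already competes against realistic negatives
    # (a queue of random vectors makes early losses meaninglessly small).
    enc_k.train()
    with nn.no_grad():
        filled = 0
        while filled < queue.size:
            advanced = 0
            for batch in two_view_batches(train_images, cfg.batch_size, aug, rng,
                                          drop_last=False):
                if batch.view_b.shape[0] % enc_config.num_bn_splits != 0:
                    continue
                queue.enqueue(enc_k.forward(batch.view_b))
                advanced += batch.view_b.shape[0]
                if filled + advanced >= queue.size:
                    break
            if advanced == 0:
                break        # no feasible batch; keep the random-init remainder
            filled += advanced

    history = []
    for epoch in range(cfg.epochs):
        optimizer.lr = cosine_lr(cfg.learning_rate, epoch, cfg.epochs)
        enc_q.train()
        enc_k.train()
        losses = []
        for batch in two_view_batches(train_images, cfg.batch_size, aug, rng,
                                      drop_last=len(train_images) >= cfg.batch_size):
            if batch.view_a.shape[0] % enc_config.num_bn_splits != 0:
                continue
            q = enc_q.forward(batch.view_a)
            with nn.no_grad():
                k = enc_k.forward(batch.view_b)
            if cfg.loss == "queue":
                loss, dq = contrastive_loss(q, k, queue.features,
                                            cfg.temperature, return_grad=True)
            else:
                loss, dq = ntxent_inbatch_loss(
                    np.concatenate([q, k]), cfg.temperature,
                    return_grad=True, pair_layout="split")
                dq = dq[:len(q)]         # keys are detached: grad via query rows only
            optimizer.zero_grad()
            enc_q.backward(dq)
            optimizer.step()
            ema_update(enc_q, enc_k, cfg.momentum)
            queue.enqueue(k)
            losses.append(loss)
        acc = np.nan
        if monitor and len(dataset.test_indices):
            acc = evaluate_knn_accuracy(enc_q, dataset, knn_cfg,
                                        image_size=cfg.image_resolution)
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(losses)) if losses else np.nan,
                        "knn_accuracy_pct": acc})
    return enc_q, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# estimator surface
# ---------------------------------------------------------------------------

class MoCoEmbedding(BaseEstimator, TransformerMixin):
    """Momentum-contrast representation learner with a transform interface.

    ``fit(X, y=None)`` trains the query encoder on a list/array of uint8 RGB
    images (labels, when given, are used only by the per-epoch KNN monitor on
    an internal held-out split — never by the loss).  ``transform(X)`` maps
    images to unit-norm ``feature_dim`` vectors from the trained encoder.
    """

    def __init__(self, arch: str = "resnet18", width: int = 64,
                 feature_dim: int = 128, num_bn_splits: int = 8,
                 batch_size: int = 128, learning_rate: float = 0.3,
                 momentum: float = 0.99, temperature: float = 0.1,
                 epochs: int = 200, queue_size: int = 4096, knn_k: int = 200,
                 knn_temperature: float = 0.1, image_resolution: int = 96,
                 monitor_fraction: float = 0.2, loss: str = "queue",
                 random_state: int = 0):
        self.arch = arch
        self.width = width
        self.feature_dim = feature_dim
        self.num_bn_splits = num_bn_splits
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.temperature = temperature
        self.epochs = epochs
        self.queue_size = queue_size
        self.knn_k = knn_k
        self.knn_temperature = knn_temperature
        self.image_resolution = image_resolution
        self.monitor_fraction = monitor_fraction
        self.loss = loss
        self.random_state = random_state

    def _configs(self) -> tuple[EncoderConfig, MoCoTrainConfig]:
        enc = EncoderConfig(arch=self.arch, feature_dim=self.feature_dim,
                            num_bn_splits=self.num_bn_splits, width=self.width,
                            seed=self.random_state)
        cfg = MoCoTrainConfig(batch_size=self.batch_size,
                              learning_rate=self.learning_rate,
                              momentum=self.momentum,
                              temperature=self.temperature, epochs=self.epochs,
                              queue_size=self.queue_size, knn_k=self.knn_k,
                              knn_temperature=self.knn_temperature,
                              image_resolution=self.image_resolution,
                              seed=self.random_state, loss=self.loss)
        return enc, cfg

    def fit(self, X, y=None):
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        enc_cfg, cfg = self._configs()
        if y is not None:
            y = np.asarray(y)
            mask = stratified_split(y, self.monitor_fraction, seed=self.random_state)
            names = [str(c) for c in np.unique(y)]
            _, encoded = np.unique(y, return_inverse=True)
            dataset = LabeledImageSet(images=images, labels=encoded,
                                      class_names=names, is_test=mask)
            monitor = True
        else:
            dataset = LabeledImageSet(images=images,
                                      labels=np.zeros(len(images), dtype=int),
                                      class_names=["unlabeled"],
                                      is_test=np.zeros(len(images), dtype=bool))
            monitor = False
        self.encoder_, self.history_ = train_moco(dataset, enc_cfg, cfg,
                                                  monitor=monitor)
        return self

    def transform(self, X):
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        return embed_images(self.encoder_, images, self.image_resolution)
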