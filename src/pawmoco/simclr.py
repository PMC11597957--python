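"""SimCLR-style single-encoder contrastive training.

One encoder plus a two-layer projection head processes both augmented views
of each batch; the in-batch NT-Xent loss treats, for every anchor row, its
paired view as the positive and the remaining 2B - 2 rows as negatives (the
anchor itself is excluded).  Optimization uses LARS with a linear
learning-rate warmup followed by cosine annealing.  No downstream classifier
is trained on this path; embeddings are exported to 2-d via t-SNE instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

from . import nn
from .data import AugmentationConfig, two_view_batches
from .datasets import LabeledImageSet
from .encoders import build_projection_head


@dataclass
class SimCLRConfig:
    batch_size: int = 256
    input_size: int = 32
    learning_rate: float = 0.2
    weight_decay: float = 1e-6
    warmup_epochs: int = 10
    total_epochs: int = 500
    temperature: float = 0.5
    tsne_perplexity: float = 50.0
    arch: str = "resnet50"
    width: int = 64                    # base channels; narrow widths for desk-scale runs
    projection_dim: int = 128
    trust_coefficient: float = 0.001
    exclude_bias_bn: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not 0 <= self.warmup_epochs < self.total_epochs:
            raise ValueError("need 0 <= warmup_epochs < total_epochs")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def ntxent_inbatch_loss(projections: np.ndarray, temperature: float,
                        return_grad: bool = False,
                        pair_layout: str = "interleaved"):
    """In-batch NT-Xent over 2B unit-norm rows.

    ``pair_layout='interleaved'`` pairs rows (2i, 2i+1);
    ``pair_layout='split'`` pairs rows (i, i+B).  Mean over the 2B anchors of
    the temperature-scaled softmax cross-entropy with the partner as target.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(projections, dtype=np.float64)
    n = p.shape[0]
    if n % 2 != 0 or n < 2:
        raise ValueError("projections must contain an even number of rows")
    if pair_layout == "interleaved":
        partner = np.arange(n) ^ 1
    elif pair_layout == "split":
        partner = (np.arange(n) + n // 2) % n
    else:
        raise ValueError("pair_layout must be 'interleaved' or 'split'")
    logits = p @ p.T / temperature
    np.fill_diagonal(logits, -np.inf)          # the anchor is never a candidate
    logp = nn.log_softmax(logits)
    loss = float(-logp[np.arange(n), partner].mean())
    if not return_grad:
        return loss
    g = np.exp(logp)
    g[np.arange(n), partner] -= 1.0
    g /= n
    dp = (g + g.T) @ p / temperature
    return loss, dp.astype(np.float32)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def warmup_cosine_lr(epoch: int, cfg: SimCLRConfig) -> float:
    """Linear warmup to base_lr, then cosine annealing to ~0."""
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError("epoch out of range")
    base = cfg.learning_rate
    w = cfg.warmup_epochs
    if w > 0 and epoch < w:
        return base * (epoch + 1) / w
    span = cfg.total_epochs - w
    return base * 0.5 * (1.0 + float(np.cos(np.pi * (epoch - w) / span)))


# ---------------------------------------------------------------------------
# model and training
# ---------------------------------------------------------------------------

class SimCLRNet(nn.Module):
    """Backbone -> projection head -> L2 normalization."""

    def __init__(self, cfg: SimCLRConfig, rng: np.random.Generator):
        super().__init__()
        # first conv modified to 3x3, stride 1, no padding (hence CIFAR-style
        # stem with stem_padding=0); batch norm is standard (1 split) here.
        self.backbone = nn.ResNet(cfg.arch, width=cfg.width, feature_dim=None,
                                  num_splits=1, cifar_stem=True, stem_padding=0,
                                  l2_normalize=False, rng=rng)
        dim = self.backbone.backbone_dim
        self.head = build_projection_head(dim, dim, cfg.projection_dim, rng=rng)
        self.l2norm = nn.L2Normalize()

    def forward(self, x):
        return self.l2norm(self.head(self.backbone(x)))

    def backward(self, dout):
        return self.backbone.backward(self.head.backward(self.l2norm.backward(dout)))

    def embed(self, x):
        """Backbone features (pre-head), the usual representation output."""
        return self.backbone(x)


def train_simclr(dataset: LabeledImageSet, cfg: SimCLRConfig,
                 ) -> tuple[SimCLRNet, pd.DataFrame]:
    """LARS-optimized NT-Xent training; history has one loss row per epoch."""
    train_idx = dataset.train_indices
    if len(train_idx) == 0:
        raise ValueError("empty train split")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 41]))
    model = SimCLRNet(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 43])))
    optimizer = nn.LARS(model.parameters(), cfg.learning_rate,
                        weight_decay=cfg.weight_decay,
                        trust_coefficient=cfg.trust_coefficient,
                        exclude_bias_bn=cfg.exclude_bias_bn)
    aug = AugmentationConfig(crop_size=cfg.input_size)
    images = dataset.subset_images(train_idx)
    batch_size = min(cfg.batch_size, max(2, len(images)))

    history = []
    for epoch in range(cfg.total_epochs):
        optimizer.lr = warmup_cosine_lr(epoch, cfg)
        model.train()
        losses = []
        for batch in two_view_batches(images, batch_size, aug, rng,
                                      drop_last=len(images) >= batch_size):
            b = batch.view_a.shape[0]
            if b < 2:
                continue
            stacked = np.empty((2 * b, *batch.view_a.shape[1:]), dtype=np.float32)
            stacked[0::2] = batch.view_a
            stacked[1::2] = batch.view_b
            proj = model.forward(stacked)
            loss, dp = ntxent_inbatch_loss(proj, cfg.temperature, return_grad=True)
            optimizer.zero_grad()
            model.backward(dp)
            optimizer.step()
            losses.append(loss)
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(losses)) if losses else np.nan})
    return model, pd.DataFrame(history)


def tsne_embed(features: np.ndarray, perplexity: float = 50.0,
               seed: int = 0) -> np.ndarray:
    """Seeded 2-d t-SNE of an (N, d) feature matrix."""
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs N > 3 * perplexity (N={n}, perplexity={perplexity})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(features)


class SimCLREmbedding(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit trains the encoder, transform embeds images."""

    def __init__(self, batch_size: int = 256, input_size: int = 32,
                 learning_rate: float = 0.2, weight_decay: float = 1e-6,
                 warmup_epochs: int = 10, total_epochs: int = 500,
                 temperature: float = 0.5, arch: str = "resnet50",
                 width: int = 64, projection_dim: int = 128,
                 random_state: int = 0):
        self.batch_size = batch_size
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.warmup_epochs = warmup_epochs
        self.total_epochs = total_epochs
        self.temperature = temperature
        self.arch = arch
        self.width = width
        self.projection_dim = projection_dim
        self.random_state = random_state

    def _cfg(self) -> SimCLRConfig:
        return SimCLRConfig(batch_size=self.batch_size, input_size=self.input_size,
                            learning_rate=self.learning_rate,
                            weight_decay=self.weight_decay,
                            warmup_epochs=self.warmup_epochs,
                            total_epochs=self.total_epochs,
                            temperature=self.temperature, arch=self.arch,
                            width=self.width, projection_dim=self.projection_dim,
                            seed=self.random_state)

    def fit(self, X, y=None):
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        dataset = LabeledImageSet(images=images,
                                  labels=np.zeros(len(images), dtype=int),
                                  class_names=["unlabeled"],
                                  is_test=np.zeros(len(images), dtype=bool))
        self.model_, self.history_ = train_simclr(dataset, self._cfg())
        return self

    def transform(self, X):
        from .knn import embed_images
        images = [np.asarray(img, dtype=np.uint8) for img in X]
        return embed_images(self.model_, images, self.input_size)
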