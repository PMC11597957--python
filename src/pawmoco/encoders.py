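"""Encoder construction: CIFAR-recipe ResNets with split BN, projection head.

The contrastive encoders follow the CIFAR ResNet recipe — a 3×3 stride-1 stem
convolution in place of the 7×7 stride-2 one, and no stem max-pool — because
inputs are small (the working resolution is 96 px and below).  Every batch
norm is a split batch norm with ``num_bn_splits`` groups, and the head maps
pooled backbone features to a ``feature_dim``-length vector which is L2
normalized so that dot products are cosine similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class EncoderConfig:
    arch: str = "resnet18"
    feature_dim: int = 128
    num_bn_splits: int = 8
    cifar_recipe: bool | None = None   # default: True for resnet18/34, False for resnet50
    l2_normalize_output: bool = True
    width: int = 64                    # base channel count; 64 is the standard recipe
    stem_padding: int | None = None    # None -> recipe default (1 for 3x3 stems)
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.num_bn_splits < 1:
            raise ValueError("num_bn_splits must be >= 1")
        if self.arch not in ("resnet18", "resnet34", "resnet50"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.cifar_recipe is None:
            self.cifar_recipe = self.arch in ("resnet18", "resnet34")

    def to_dict(self) -> dict:
        return dict(arch=self.arch, feature_dim=self.feature_dim,
                    num_bn_splits=self.num_bn_splits, cifar_recipe=self.cifar_recipe,
                    l2_normalize_output=self.l2_normalize_output, width=self.width,
                    stem_padding=self.stem_padding, seed=self.seed)


def build_encoder(config: EncoderConfig,
                  rng: np.random.Generator | None = None) -> nn.ResNet:
    """Instantiate the configured backbone; weights are seeded random."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return nn.ResNet(
        config.arch,
        width=config.width,
        feature_dim=config.feature_dim,
        num_splits=config.num_bn_splits,
        cifar_stem=config.cifar_recipe,
        stem_padding=config.stem_padding,
        l2_normalize=config.l2_normalize_output,
        rng=rng,
    )


def build_projection_head(in_dim: int = 2048, hidden: int = 2048,
                          out_dim: int = 128,
                          rng: np.random.Generator | None = None) -> nn.Sequential:
    """Two-layer perceptron head: linear -> ReLU -> linear."""
    if min(in_dim, hidden, out_dim) < 1:
        raise ValueError("projection head dimensions must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    return nn.Sequential(
        nn.Linear(in_dim, hidden, rng=rng),
        nn.ReLU(),
        nn.Linear(hidden, out_dim, rng=rng),
    )


def split_batch_norm_forward(x: np.ndarray, num_splits: int, training: bool,
                             state: nn.BatchNorm2d) -> np.ndarray:
    """Functional view of split BN using an existing layer's parameters/stats."""
    if state.num_splits != num_splits:
        raise ValueError("state was built with a different num_splits")
    was_training = state.training
    state.training = training
    try:
        with nn.no_grad():
            return state.forward(x)
    finally:
        state.training = was_training


def count_parameters(module: nn.Module) -> int:
    """Total learnable scalar count (introspection helper)."""
    return module.num_parameters()
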