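"""ResNet backbones (18/34 basic-block, 50 bottleneck) on the numpy engine.

Two stem recipes are supported:

* ImageNet recipe — 7×7 stride-2 stem convolution followed by a 3×3 stride-2
  max pool (used by the supervised ResNet50 baseline).
* CIFAR recipe — 3×3 stride-1 stem convolution and *no* stem pooling, the
  standard adaptation for small inputs; this is the recipe used for the
  contrastive encoders.

Every batch-norm layer is a (split) ``BatchNorm2d``; ``num_splits=1`` is plain
batch norm.  The final head is global average pooling, an optional fully
connected layer to ``feature_dim`` and optional L2 normalization of rows.
"""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, L2Normalize, Linear,
                     MaxPool2d, ReLU)


class BasicBlock(Module):
    expansion = 1

    def __init__(self, in_ch: int, out_ch: int, stride: int, num_splits: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch, num_splits)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch, num_splits)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng)
            self.down_bn = BatchNorm2d(out_ch, num_splits)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        identity = self.down_bn(self.down_conv(x)) if self.down_conv is not None else x
        return self.relu_out(out + identity)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        if self.down_conv is not None:
            d_skip = self.down_conv.backward(self.down_bn.backward(d))
        else:
            d_skip = d
        return d_main + d_skip


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int, num_splits: int,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv2d(in_ch, mid_ch, 1, 1, 0, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch, num_splits)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride, 1, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch, num_splits)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid_ch, out_ch, 1, 1, 0, rng=rng)
        self.bn3 = BatchNorm2d(out_ch, num_splits)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng)
            self.down_bn = BatchNorm2d(out_ch, num_splits)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        identity = self.down_bn(self.down_conv(x)) if self.down_conv is not None else x
        return self.relu_out(out + identity)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        d_main = self.bn3.backward(d)
        d_main = self.conv3.backward(d_main)
        d_main = self.relu2.backward(d_main)
        d_main = self.bn2.backward(d_main)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        d_main = self.conv1.backward(d_main)
        if self.down_conv is not None:
            d_skip = self.down_conv.backward(self.down_bn.backward(d))
        else:
            d_skip = d
        return d_main + d_skip


_STAGE_BLOCKS = {
    "resnet18": (BasicBlock, (2, 2, 2, 2)),
    "resnet34": (BasicBlock, (3, 4, 6, 3)),
    "resnet50": (Bottleneck, (3, 4, 6, 3)),
}


class ResNet(Module):
    """Configurable ResNet emitting (B, feature_dim) vectors.

    ``feature_dim=None`` drops the fully connected head and returns the pooled
    backbone features (used when an external projection head follows).
    """

    def __init__(self, arch: str = "resnet18", *, width: int = 64,
                 feature_dim: int | None = 128, num_splits: int = 1,
                 cifar_stem: bool = True, stem_padding: int | None = None,
                 l2_normalize: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if arch not in _STAGE_BLOCKS:
            raise ValueError(f"unknown arch {arch!r}; expected one of {sorted(_STAGE_BLOCKS)}")
        rng = rng if rng is not None else np.random.default_rng(0)
        block_cls, counts = _STAGE_BLOCKS[arch]
        self.arch = arch
        self.width = width
        self.cifar_stem = cifar_stem
        if cifar_stem:
            pad = 1 if stem_padding is None else stem_padding
            self.stem_conv = Conv2d(3, width, 3, 1, pad, rng=rng)
            self.stem_pool = None
        else:
            pad = 3 if stem_padding is None else stem_padding
            self.stem_conv = Conv2d(3, width, 7, 2, pad, rng=rng)
            self.stem_pool = MaxPool2d(3, 2, 1)
        self.stem_bn = BatchNorm2d(width, num_splits)
        self.stem_relu = ReLU()
        self.stages = []
        in_ch = width
        for i, n_blocks in enumerate(counts):
            out_ch = width * (2 ** i)
            stride = 1 if i == 0 else 2
            blocks = []
            for j in range(n_blocks):
                blocks.append(block_cls(in_ch, out_ch, stride if j == 0 else 1,
                                        num_splits, rng))
                in_ch = out_ch * block_cls.expansion
            self.stages.append(blocks)
        self.backbone_dim = in_ch
        self.pool = GlobalAvgPool()
        self.fc = Linear(in_ch, feature_dim, rng=rng) if feature_dim is not None else None
        self.feature_dim = feature_dim if feature_dim is not None else in_ch
        self.l2norm = L2Normalize() if l2_normalize else None

    def forward(self, x):
        out = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        if self.stem_pool is not None:
            out = self.stem_pool(out)
        for stage in self.stages:
            for block in stage:
                out = block.forward(out)
        out = self.pool(out)
        if self.fc is not None:
            out = self.fc(out)
        if self.l2norm is not None:
            out = self.l2norm(out)
        return out

    def backward(self, dout):
        if self.l2norm is not None:
            dout = self.l2norm.backward(dout)
        if self.fc is not None:
            dout = self.fc.backward(dout)
        dout = self.pool.backward(dout)
        for stage in reversed(self.stages):
            for block in reversed(stage):
                dout = block.backward(dout)
        if self.stem_pool is not None:
            dout = self.stem_pool.backward(dout)
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(dout)))
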