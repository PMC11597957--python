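"""Loading class-per-folder image trees and the two-view contrastive pipeline.

The contrastive augmentation chain is: random resized crop -> random
horizontal flip -> random color jitter (applied as a whole with probability
``p_jitter``) -> conversion to a normalized float32 CHW array.  Applying the
chain twice independently to one image yields the positive pair.
Normalization is always the last step and is applied exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image, UnidentifiedImageError

from .datasets import LabeledImageSet, stratified_split

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".gif", ".webp"}

#: ImageNet channel statistics, the single normalization convention used
#: across the package.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class AugmentationConfig:
    crop_size: int = 96
    crop_scale: tuple[float, float] = (0.2, 1.0)
    p_hflip: float = 0.5
    jitter: tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.1)
    p_jitter: float = 0.8
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if not (0.0 <= self.p_hflip <= 1.0 and 0.0 <= self.p_jitter <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.crop_scale
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale must satisfy 0 < min <= max <= 1")
        if any(v < 0 for v in self.jitter):
            raise ValueError("jitter components must be non-negative")


@dataclass
class TwoViewBatch:
    view_a: np.ndarray       # (B, 3, H, W) float32
    view_b: np.ndarray       # (B, 3, H, W) float32
    indices: np.ndarray      # (B,) dataset indices

    def __post_init__(self):
        if self.view_a.shape != self.view_b.shape:
            raise ValueError("paired views must have identical shape")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_image_dataset(root_dir: str | Path, test_fraction: float = 0.2,
                       seed: int = 0) -> LabeledImageSet:
    """Read a class-per-subdirectory tree into memory.

    Subdirectory names become class names; class indices follow lexicographic
    order, 0-based.  Undecodable files are skipped with a warning.  The
    train/test split is stratified per class and deterministic in ``seed``.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"need >= 2 class subdirectories under {root}")

    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    class_names = [d.name for d in class_dirs]
    for c, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        n_ok = 0
        for p in files:
            try:
                with Image.open(p) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping undecodable image %s: %s", p, exc)
                continue
            images.append(arr)
            labels.append(c)
            paths.append(str(p))
            n_ok += 1
        if n_ok == 0:
            raise ValueError(f"class folder {d} contains no decodable images")

    labels_arr = np.asarray(labels)
    mask = stratified_split(labels_arr, test_fraction, seed)
    return LabeledImageSet(images=images, labels=labels_arr,
                           class_names=class_names, is_test=mask, paths=paths)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def normalize_chw(img: Image.Image | np.ndarray, mean, std) -> np.ndarray:
    """uint8 HWC image -> normalized float32 CHW array."""
    arr = np.asarray(img, dtype=np.float32) / 255.0
    arr = (arr - np.asarray(mean, dtype=np.float32)) / np.asarray(std, dtype=np.float32)
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def _random_resized_crop(img: Image.Image, size: int, scale: tuple[float, float],
                         rng: np.random.Generator) -> Image.Image:
    """Area/aspect-sampled crop, resized (up-scaling when needed) to size×size."""
    w, h = img.size
    area = w * h
    log_ratio = (np.log(3 / 4), np.log(4 / 3))
    for _ in range(10):
        target_area = area * rng.uniform(scale[0], scale[1])
        aspect = float(np.exp(rng.uniform(*log_ratio)))
        cw = int(round(np.sqrt(target_area * aspect)))
        ch = int(round(np.sqrt(target_area / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            left = int(rng.integers(0, w - cw + 1))
            top = int(rng.integers(0, h - ch + 1))
            crop = img.crop((left, top, left + cw, top + ch))
            return crop.resize((size, size), Image.BILINEAR)
    # fallback: center crop of the largest fitting square
    side = min(w, h)
    left, top = (w - side) // 2, (h - side) // 2
    return img.crop((left, top, left + side, top + side)).resize((size, size),
                                                                 Image.BILINEAR)


def _color_jitter(img: Image.Image, jitter, rng: np.random.Generator) -> Image.Image:
    from PIL import ImageEnhance

    b, c, s, h = jitter
    if b > 0:
        img = ImageEnhance.Brightness(img).enhance(rng.uniform(max(0, 1 - b), 1 + b))
    if c > 0:
        img = ImageEnhance.Contrast(img).enhance(rng.uniform(max(0, 1 - c), 1 + c))
    if s > 0:
        img = ImageEnhance.Color(img).enhance(rng.uniform(max(0, 1 - s), 1 + s))
    if h > 0:
        shift = rng.uniform(-h, h)
        hsv = np.array(img.convert("HSV"), dtype=np.int16)
        hsv[..., 0] = (hsv[..., 0] + int(round(shift * 255))) % 256
        img = Image.fromarray(hsv.astype(np.uint8), mode="HSV").convert("RGB")
    return img


def _augment_once(img: Image.Image, config: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    view = _random_resized_crop(img, config.crop_size, config.crop_scale, rng)
    if rng.random() < config.p_hflip:
        view = view.transpose(Image.FLIP_LEFT_RIGHT)
    if rng.random() < config.p_jitter and any(v > 0 for v in config.jitter):
        view = _color_jitter(view, config.jitter, rng)
    return normalize_chw(view, config.mean, config.std)


def two_view_augment(image: np.ndarray | Image.Image, config: AugmentationConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented, normalized views of one image."""
    img = image if isinstance(image, Image.Image) else Image.fromarray(image)
    return _augment_once(img, config, rng), _augment_once(img, config, rng)


def eval_transform(image: np.ndarray | Image.Image, size: int,
                   mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """Deterministic resize to size×size plus normalization."""
    img = image if isinstance(image, Image.Image) else Image.fromarray(image)
    return normalize_chw(img.resize((size, size), Image.BILINEAR), mean, std)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def two_view_batches(images: list[np.ndarray], batch_size: int,
                     config: AugmentationConfig, rng: np.random.Generator,
                     drop_last: bool = True) -> Iterator[TwoViewBatch]:
    """Shuffled two-view minibatches over a list of uint8 images."""
    order = rng.permutation(len(images))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        if drop_last and len(idx) < batch_size:
            break
        pairs = [two_view_augment(images[i], config, rng) for i in idx]
        yield TwoViewBatch(
            view_a=np.stack([p[0] for p in pairs]),
            view_b=np.stack([p[1] for p in pairs]),
            indices=idx,
        )


def eval_batch(images: list[np.ndarray], size: int,
               mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """Deterministic (N, 3, size, size) batch, in dataset order (no shuffle)."""
    return np.stack([eval_transform(img, size, mean, std) for img in images])
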