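"""Synthetic balanced image datasets standing in for withheld animal photos.

Real animal-emotion corpora encode class identity in pose and expression and
bury it under nuisance variation (background, lighting, viewpoint).  The
generator reproduces that *statistical* structure with parametric drawings:
each class owns a distinct body-ellipse orientation, an "ear" triangle
placement and a hue band, perturbed by background texture, brightness jitter,
pixel noise and small geometric noise.  ``signal_strength`` interpolates
between pure noise classes (0) and fully deterministic class features (1);
``nuisance_strength`` scales the label-independent variation.  Balanced
classes make uniform guessing accuracy exactly ``100 / n_classes`` percent.

Everything is reproducible from the config seed, per image, so datasets are
byte-identical across runs and machines.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .datasets import LabeledImageSet, stratified_split

#: Panksepp's seven primal mammalian affective systems, used as class names
#: whenever a 7-class dataset is generated.
PANKSEPP_EMOTIONS = ("Exploring", "Sadness", "Playing", "Rage", "Fear",
                     "Affectionate", "Lust")


@dataclass
class SyntheticConfig:
    n_classes: int = 7
    n_per_class: int = 300
    image_size: int = 96
    signal_strength: float = 0.9
    nuisance_strength: float = 0.3
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for name in ("signal_strength", "nuisance_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def class_names(self) -> list[str]:
        if self.n_classes == 7:
            return list(PANKSEPP_EMOTIONS)
        return [f"class_{i}" for i in range(self.n_classes)]


def chance_accuracy(n_classes: int) -> float:
    """Expected percent accuracy of uniform guessing over balanced classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 100.0 / n_classes


def _class_parameters(c: int, k: int) -> dict:
    """Deterministic per-class generative rule parameters."""
    return {
        "hue": c / k,
        "angle": np.pi * (c + 0.5) / k,            # body-ellipse orientation
        "ear_phase": 2.0 * np.pi * c / k,          # ear placement around body
    }


def render_image(c: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one (image_size, image_size, 3) uint8 image for class ``c``."""
    n = cfg.image_size
    sig, nui = cfg.signal_strength, cfg.nuisance_strength
    par = _class_parameters(c, cfg.n_classes)

    # background: mid grey plus low-frequency nuisance texture
    img = np.full((n, n, 3), 0.45, dtype=np.float64)
    if nui > 0:
        coarse = rng.normal(0.0, 0.18 * nui, size=(4, 4, 3))
        tex = np.array(Image.fromarray(
            np.uint8(np.clip(coarse + 0.5, 0, 1) * 255)).resize((n, n), Image.BILINEAR))
        img += tex / 255.0 - 0.5

    # class-dependent geometry, degraded as signal_strength drops
    angle = par["angle"] + (1 - sig) * rng.uniform(-np.pi / 2, np.pi / 2) \
        + rng.uniform(-0.04, 0.04) * np.pi
    hue = (par["hue"] + (1 - sig) * rng.uniform(-0.5, 0.5)
           + rng.uniform(-0.02, 0.02)) % 1.0
    ear_phase = par["ear_phase"] + (1 - sig) * rng.uniform(-np.pi, np.pi)

    cx = 0.5 + rng.uniform(-0.04, 0.04) * (1 + nui)
    cy = 0.5 + rng.uniform(-0.04, 0.04) * (1 + nui)
    ax = 0.32 * (1 + rng.uniform(-0.05, 0.05))
    ay = 0.17 * (1 + rng.uniform(-0.05, 0.05))

    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
    ca, sa = np.cos(angle), np.sin(angle)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = -(xx - cx) * sa + (yy - cy) * ca
    body = (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0

    body_rgb = np.array(colorsys.hsv_to_rgb(hue, 0.85, 0.85))
    img[body] = body_rgb

    # "ear": small dark triangle at a class-specific position on the body rim
    ex = cx + 0.26 * np.cos(ear_phase + angle)
    ey = cy + 0.26 * np.sin(ear_phase + angle)
    esz = 0.09
    tri = ((yy >= ey - esz) & (yy <= ey)
           & (np.abs(xx - ex) <= (yy - (ey - esz)) * 0.9))
    ear_rgb = np.array(colorsys.hsv_to_rgb(hue, 0.9, 0.45))
    img[tri] = ear_rgb

    # nuisance lighting and pixel noise
    img *= 1.0 + nui * rng.uniform(-0.3, 0.3)
    img += rng.normal(0.0, 0.015 + 0.05 * nui, size=img.shape)
    return np.uint8(np.clip(img, 0, 1) * 255)


def generate_synthetic_emotion_dataset(config: SyntheticConfig,
                                       out_dir: str | Path | None = None,
                                       ) -> LabeledImageSet:
    """Generate a balanced class-per-folder dataset (PNG when ``out_dir`` set).

    Writes ``n_classes`` subdirectories named after the class labels, each with
    exactly ``n_per_class`` PNG files, plus a ``manifest.csv`` with columns
    path, class_index, class_name, split.  Returns the in-memory dataset with
    its seeded stratified train/test assignment.
    """
    names = config.class_names()
    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] | None = [] if out_dir is not None else None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for c, name in enumerate(names):
        cls_dir = None
        if out_dir is not None:
            cls_dir = out_dir / name
            cls_dir.mkdir(exist_ok=True)
        for i in range(config.n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, c, i]))
            img = render_image(c, config, rng)
            images.append(img)
            labels.append(c)
            if cls_dir is not None:
                path = cls_dir / f"{name.lower()}_{i:04d}.png"
                Image.fromarray(img).save(path, format="PNG")
                paths.append(str(path))

    labels_arr = np.asarray(labels)
    mask = stratified_split(labels_arr, config.test_fraction,
                            seed=int(np.random.SeedSequence(
                                [config.seed, 982451653]).generate_state(1)[0] % (2**31)))
    dataset = LabeledImageSet(images=images, labels=labels_arr,
                              class_names=names, is_test=mask, paths=paths)
    if out_dir is not None:
        dataset.manifest().to_csv(Path(out_dir) / "manifest.csv", index=False)
    return dataset
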