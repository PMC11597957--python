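"""The labeled image collection shared by every pipeline in the package.

Images are held in memory as uint8 RGB arrays (datasets at the scale this
package targets — a few thousand small images — fit comfortably), optionally
with their on-disk paths.  The train/test split is stored per record and is
produced once, stratified by class, from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LabeledImageSet:
    images: list[np.ndarray]            # each (H, W, 3) uint8
    labels: np.ndarray                  # (N,) int class indices
    class_names: list[str]
    is_test: np.ndarray                 # (N,) bool
    paths: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.is_test = np.asarray(self.is_test, dtype=bool)
        n = len(self.images)
        if not (len(self.labels) == len(self.is_test) == n):
            raise ValueError("images, labels and split flags must have equal length")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("class indices out of range")
        counts = np.bincount(self.labels, minlength=len(self.class_names))
        if n and (counts == 0).any():
            raise ValueError("every class must be non-empty")

    # -- basic accessors ----------------------------------------------
    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_test)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_test)

    def subset_images(self, indices: np.ndarray) -> list[np.ndarray]:
        return [self.images[i] for i in indices]

    def manifest(self) -> pd.DataFrame:
        paths = self.paths if self.paths is not None else [""] * len(self)
        return pd.DataFrame({
            "path": paths,
            "class_index": self.labels,
            "class_name": [self.class_names[c] for c in self.labels],
            "split": np.where(self.is_test, "test", "train"),
        })


def stratified_split(labels: np.ndarray, test_fraction: float,
                     seed: int) -> np.ndarray:
    """Per-class held-out assignment; returns a boolean test mask.

    The test count per class is ``round(n * test_fraction)``, at least 1
    whenever the class has more than one record.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = int(round(len(idx) * test_fraction))
        if n_test == 0 and len(idx) > 1:
            n_test = 1
        n_test = min(n_test, len(idx) - 1) if len(idx) > 1 else 0
        chosen = rng.choice(idx, size=n_test, replace=False)
        mask[chosen] = True
    return mask
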