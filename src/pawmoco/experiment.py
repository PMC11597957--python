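"""Config-file driven experiment orchestration.

An experiment config is a nested mapping (usually loaded from YAML) with a
single global ``seed``, a ``data`` block (either a class-per-folder ``dir``
or a ``synthetic`` generator block), per-pipeline hyperparameter blocks
(``encoder``, ``moco``, ``simclr``, ``supervised``, ``knn``) and a ``tasks``
list choosing what to run.  Every run directory receives a JSON snapshot of
the resolved config, a log file, history CSVs, checkpoints, reports and
plots, so a run is reproducible from its directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .data import load_image_dataset
from .datasets import LabeledImageSet
from .encoders import EncoderConfig
from .knn import KnnConfig, classification_report, embed_images, knn_predict, MemoryBank
from .moco import MoCoTrainConfig, train_moco
from .reporting import (make_run_dir, plot_history, save_checkpoint,
                        save_history, setup_run_logging, write_config_snapshot)
from .simclr import SimCLRConfig, train_simclr, tsne_embed
from .supervised import (SupervisedConfig, compare_supervised_vs_unsupervised,
                         predict_labels, train_supervised)
from .synthetic import SyntheticConfig, generate_synthetic_emotion_dataset

logger = logging.getLogger(__name__)

DEFAULT_TASKS = ("train_moco", "evaluate")


@dataclass
class ExperimentConfig:
    seed: int = 0
    out_dir: str = "runs"
    name: str = "experiment"
    tasks: tuple[str, ...] = DEFAULT_TASKS
    data: dict = field(default_factory=dict)
    encoder: dict = field(default_factory=dict)
    moco: dict = field(default_factory=dict)
    simclr: dict = field(default_factory=dict)
    supervised: dict = field(default_factory=dict)
    knn: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.tasks = tuple(cfg.tasks)
        return cfg

    def to_dict(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, "name": self.name,
                "tasks": list(self.tasks), "data": self.data,
                "encoder": self.encoder, "moco": self.moco,
                "simclr": self.simclr, "supervised": self.supervised,
                "knn": self.knn}


def _load_dataset(cfg: ExperimentConfig, run_dir: Path) -> LabeledImageSet:
    data = dict(cfg.data)
    test_fraction = data.get("test_fraction", 0.2)
    if "dir" in data:
        return load_image_dataset(data["dir"], test_fraction, seed=cfg.seed)
    synth = dict(data.get("synthetic", {}))
    synth.setdefault("seed", cfg.seed)
    synth.setdefault("test_fraction", test_fraction)
    out = run_dir / "dataset" if data.get("write_images", False) else None
    return generate_synthetic_emotion_dataset(SyntheticConfig(**synth), out)


def run_experiment(config: ExperimentConfig | dict) -> Path:
    """Execute the configured pipeline(s); returns the run directory."""
    if isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    run_dir = make_run_dir(config.out_dir, config.name)
    write_config_snapshot(run_dir, config.to_dict())
    setup_run_logging(run_dir)
    logger.info("run directory: %s", run_dir)

    dataset = _load_dataset(config, run_dir)
    logger.info("dataset: %d images, %d classes", len(dataset), dataset.n_classes)

    enc_cfg = EncoderConfig(**{"seed": config.seed, **config.encoder})
    knn_cfg = KnnConfig(**{"num_classes": dataset.n_classes, **config.knn})
    encoder = None
    moco_cfg = MoCoTrainConfig(**{"seed": config.seed, **config.moco})

    for task in config.tasks:
        if task == "train_moco":
            encoder, history = train_moco(dataset, enc_cfg, moco_cfg)
            save_history(history, run_dir / "moco_history.csv")
            save_checkpoint(run_dir / "moco_encoder.npz", encoder,
                            {"encoder": enc_cfg.to_dict()})
            plot_history(run_dir / "moco_history.csv", run_dir)
        elif task == "evaluate":
            if encoder is None:
                raise ValueError("'evaluate' requires a prior 'train_moco' task")
            _evaluate_moco(encoder, dataset, knn_cfg, moco_cfg, run_dir)
        elif task == "train_simclr":
            simclr_cfg = SimCLRConfig(**{"seed": config.seed, **config.simclr})
            model, history = train_simclr(dataset, simclr_cfg)
            save_history(history, run_dir / "simclr_history.csv")
            plot_history(run_dir / "simclr_history.csv", run_dir)
            _tsne_export(model, dataset, simclr_cfg, run_dir)
        elif task == "train_supervised":
            sup_cfg = SupervisedConfig(**{"seed": config.seed, **config.supervised})
            model, history = train_supervised(dataset, sup_cfg)
            save_history(history, run_dir / "supervised_history.csv")
            plot_history(run_dir / "supervised_history.csv", run_dir)
            pred = predict_labels(model, dataset.subset_images(dataset.test_indices),
                                  sup_cfg)
            report = classification_report(pred, dataset.labels[dataset.test_indices],
                                           dataset.class_names)
            report.to_csv(run_dir / "supervised_report.csv")
            logger.info("supervised accuracy: %.2f%%", report.accuracy)
        elif task == "compare":
            sup_cfg = SupervisedConfig(**{"seed": config.seed, **config.supervised})
            table = compare_supervised_vs_unsupervised(dataset, sup_cfg,
                                                       enc_cfg, moco_cfg)
            table.to_csv(run_dir / "comparison.csv", index=False)
        else:
            raise ValueError(f"unknown task {task!r}")
    return run_dir


def _evaluate_moco(encoder, dataset, knn_cfg, moco_cfg, run_dir: Path) -> None:
    test_idx = dataset.test_indices
    bank = MemoryBank(
        features=embed_images(encoder, dataset.subset_images(dataset.train_indices),
                              moco_cfg.image_resolution),
        labels=dataset.labels[dataset.train_indices])
    pred, _ = knn_predict(
        embed_images(encoder, dataset.subset_images(test_idx),
                     moco_cfg.image_resolution), bank, knn_cfg)
    report = classification_report(pred, dataset.labels[test_idx],
                                   dataset.class_names)
    report.to_csv(run_dir / "knn_report.csv")
    logger.info("KNN accuracy: %.2f%%", report.accuracy)


def _tsne_export(model, dataset, simclr_cfg: SimCLRConfig, run_dir: Path) -> None:
    feats = embed_images(model, dataset.images, simclr_cfg.input_size)
    if len(feats) > 3 * simclr_cfg.tsne_perplexity:
        coords = tsne_embed(feats, simclr_cfg.tsne_perplexity, simclr_cfg.seed)
        pd.DataFrame({
            "index": np.arange(len(coords)),
            "label": [dataset.class_names[c] for c in dataset.labels],
            "x": coords[:, 0], "y": coords[:, 1],
        }).to_csv(run_dir / "tsne.csv", index=False)
    else:
        logger.warning("skipping t-SNE: N=%d too small for perplexity %.0f",
                       len(feats), simclr_cfg.tsne_perplexity)
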