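"""Run directories, history CSVs, checkpoints and loss/accuracy plots."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import nn  # noqa: E402

logger = logging.getLogger(__name__)


def make_run_dir(base: str | Path, name: str = "run") -> Path:
    """Create base/name, appending -1, -2, ... if it already exists."""
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    candidate = base / name
    suffix = 0
    while candidate.exists():
        suffix += 1
        candidate = base / f"{name}-{suffix}"
    candidate.mkdir()
    return candidate


def write_config_snapshot(run_dir: str | Path, config: dict) -> Path:
    path = Path(run_dir) / "config.json"
    path.write_text(json.dumps(config, indent=2, default=str) + "\n")
    return path


def setup_run_logging(run_dir: str | Path) -> Path:
    log_path = Path(run_dir) / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("pawmoco").addHandler(handler)
    logging.getLogger("pawmoco").setLevel(logging.INFO)
    return log_path


def save_history(history: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    history.to_csv(path, index=False)
    return path


def save_checkpoint(path: str | Path, model: nn.Module, config: dict) -> Path:
    """Serialize model state plus its build config into one .npz file."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(config, default=str),
             **{f"state/{k}": v for k, v in state.items()})
    return path


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Return (state_dict, config) from a checkpoint file."""
    with np.load(Path(path), allow_pickle=False) as data:
        config = json.loads(str(data["__config__"]))
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    return state, config


def plot_history(history_csv: str | Path, out_dir: str | Path) -> list[Path]:
    """One PNG per numeric series (loss, accuracy) in a history CSV."""
    history_csv = Path(history_csv)
    df = pd.read_csv(history_csv)
    if df.empty or "epoch" not in df.columns:
        raise ValueError(f"malformed or empty history CSV: {history_csv}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for column in df.columns:
        if column == "epoch" or not np.issubdtype(df[column].dtype, np.number):
            continue
        series = df[["epoch", column]].dropna()
        if series.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(series["epoch"], series[column], marker="o", markersize=2)
        ax.set_xlabel("epoch")
        ax.set_ylabel(column)
        ax.set_title(column.replace("_", " "))
        fig.tight_layout()
        path = out_dir / f"{history_csv.stem}_{column}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if not written:
        raise ValueError(f"no plottable series in {history_csv}")
    return written
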