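"""Losses returning (scalar, gradient-with-respect-to-logits)."""

from __future__ import annotations

import numpy as np


def log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy with integer targets; returns (loss, dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    n = logits.shape[0]
    logp = log_softmax(logits)
    loss = -logp[np.arange(n), targets].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(np.float32)
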