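"""Minimal layer-wise reverse-mode engine for feed-forward conv nets.

Every layer owns its parameters, caches what its backward pass needs during
``forward`` (only while gradients are enabled), and implements ``backward``
returning the gradient with respect to its input while accumulating parameter
gradients in place.  This is deliberately much smaller than a general autodiff
system: the architectures used here (ResNet variants plus MLP heads) are plain
chains with residual additions, which the block modules handle explicitly.

All parameters and activations are float32.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterator

import numpy as np

_GRAD_ENABLED: list[bool] = [True]


@contextmanager
def no_grad():
    """Disable backward caching (used for the momentum/key encoder)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Parameter:
    """A learnable array with its gradient buffer.

    ``adapt``/``decay`` flags mark whether LARS layer-adaptation and weight
    decay apply (biases and batch-norm affine parameters conventionally opt
    out of both).
    """

    __slots__ = ("data", "grad", "adapt", "decay")

    def __init__(self, data: np.ndarray, *, adapt: bool = True, decay: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.adapt = adapt
        self.decay = decay

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size


def _walk_children(value, path: str):
    """Yield (name, module) pairs from attributes, recursing through
    arbitrarily nested lists/tuples (e.g. a list of stages of blocks)."""
    if isinstance(value, Module):
        yield from value.named_modules(f"{path}.")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk_children(item, f"{path}.{i}")


class Module:
    """Base class: training flag, parameter/buffer traversal, state dicts."""

    #: names of plain-ndarray attributes persisted in state_dict (running stats)
    buffer_names: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, value in vars(self).items():
            yield from _walk_children(value, f"{prefix}{name}")

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for path, mod in self.named_modules():
            for name, value in vars(mod).items():
                if isinstance(value, Parameter):
                    yield f"{path}{name}", value

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for path, mod in self.named_modules():
            for name in mod.buffer_names:
                yield f"{path}{name}", getattr(mod, name)

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, mod in self.named_modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            src = np.asarray(state[name], dtype=np.float32)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {p.data.shape}")
            p.data[...] = src
        for path, mod in self.named_modules():
            for bname in mod.buffer_names:
                full = f"{path}{bname}"
                getattr(mod, bname)[...] = np.asarray(state[full], dtype=np.float32)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- computation (subclasses override) ------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def __getitem__(self, i):
        return self.layers[i]

    def __len__(self):
        return len(self.layers)
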