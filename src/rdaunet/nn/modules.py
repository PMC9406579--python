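"""Layer modules built on the autodiff tensor.

Follows the familiar Module idiom: parameters are discovered by attribute
walk, ``state_dict``/``load_state_dict`` round-trip numpy arrays, and
``train()``/``eval()`` toggle batch-norm statistics.  A module call can be
traced (see :func:`trace`) to recover the per-node shape/parameter manifest
used by the architecture description tools.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np

from .conv_ops import conv2d, conv_transpose2d_2x, max_pool2d_2x, upsample_nearest_2x
from .tensor import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "ConvTranspose2d2x",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest2x",
    "trace",
]

_TRACE: list | None = None


@contextlib.contextmanager
def trace():
    """Context manager recording (module, output_shape) for every leaf call."""
    global _TRACE
    prev, _TRACE = _TRACE, []
    try:
        yield _TRACE
    finally:
        _TRACE = prev


class Module:
    """Base class: parameter discovery, mode switching, serialization."""

    def __init__(self) -> None:
        self.training = True

    # ------------------------------------------------------------- traversal
    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix or "root", self
        for name, child in self.named_children():
            yield from child.named_modules(f"{prefix}.{name}" if prefix else name)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self.named_children():
            yield from child.named_parameters(f"{prefix}.{name}" if prefix else name)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ------------------------------------------------------------------ mode
    def train(self) -> "Module":
        self.training = True
        for _, child in self.named_children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self.named_children():
            child.eval()
        return self

    # --------------------------------------------------------- serialization
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self.named_modules():
            for key, buf in getattr(mod, "_buffers", {}).items():
                state[f"{name}.{key}"] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {
            f"{name}.{key}": (mod, key)
            for name, mod in self.named_modules()
            for key in getattr(mod, "_buffers", {})
        }
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(value, dtype=params[key].data.dtype).copy()
            elif key in buffers:
                mod, bkey = buffers[key]
                mod._buffers[bkey] = np.asarray(
                    value, dtype=mod._buffers[bkey].dtype
                ).copy()
            else:
                raise KeyError(f"unexpected state entry {key}")

    # ------------------------------------------------------------------ call
    def __call__(self, *args: Tensor) -> Tensor:
        out = self.forward(*args)
        if _TRACE is not None and not list(self.named_children()):
            _TRACE.append((self, out.shape))
        return out

    def forward(self, *args: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = k, stride, padding
        self.weight = Tensor(
            _he_normal(rng, (out_channels, in_channels, k, k), fan_in), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d2x(Module):
    """Kernel-2 stride-2 up-convolution (exact 2x spatial doubling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = Tensor(
            _he_normal(rng, (in_channels, out_channels, 2, 2), in_channels * 4),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.channels, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(-1)
            ).astype(self._buffers["running_mean"].dtype)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * unbiased
            ).astype(self._buffers["running_var"].dtype)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d_2x(x)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest_2x(x)
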