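"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv3d, conv_transpose3d

__all__ = [
    "Parameter", "Module", "ModuleList", "Linear", "Conv3d",
    "ConvTranspose3d", "BatchNorm3d", "LayerNorm",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery and state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(val, dict):
                for item in val.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{k}.")
            elif name.startswith("buf_") and isinstance(val, np.ndarray):
                yield full, val

    # -- modes / state --------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = arr.copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name!r}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m):
        self.items.append(m)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (in_features, out_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """3D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if out_channels <= 0:
            raise ValueError("out_channels must be positive")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size ** 3
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std,
                                           (out_channels, in_channels,
                                            kernel_size, kernel_size,
                                            kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.padding = kernel_size // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.padding)


class ConvTranspose3d(Module):
    """Transposed convolution, kernel 2 / stride 2 (doubles each spatial dim)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / in_channels)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (in_channels, out_channels, 2, 2, 2)
                                           ).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    """Batch normalization over (batch, spatial) per channel.

    Training mode uses batch statistics and updates running estimates;
    eval mode uses the frozen running statistics.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.buf_running_mean = np.zeros(num_features, dtype=dtype)
        self.buf_running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.buf_running_mean[...] = ((1 - m) * self.buf_running_mean
                                          + m * mu.data.reshape(-1))
            self.buf_running_var[...] = ((1 - m) * self.buf_running_var
                                         + m * var.data.reshape(-1))
            xhat = xc / (var + self.eps).sqrt()
        else:
            shape = (1, -1, 1, 1, 1)
            mu = Tensor(self.buf_running_mean.reshape(shape))
            sd = Tensor(np.sqrt(self.buf_running_var + self.eps).reshape(shape))
            xhat = (x - mu) / sd
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta
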