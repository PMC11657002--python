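"""Neural-network layers on top of the autodiff tensor.

Modules follow the familiar container conventions: attribute discovery for
submodules and parameters, ``train()`` / ``eval()`` modes, and a flat
``state_dict`` of numpy arrays for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d

_init_rng = np.random.default_rng(0)


def seed(value: int) -> None:
    """Re-seed the parameter-initialisation stream (call before building nets)."""
    global _init_rng
    _init_rng = np.random.default_rng(value)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in self.__dict__.values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{full}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, attr in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(attr, np.ndarray):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.buffers(f"{full}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{full}.{i}.")

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer::{name}": b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                target = buffers[key[len("buffer::") :]]
                target[...] = value
            else:
                if params[key].shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            _init_rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(_init_rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data
            self.running_var[...] = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            from . import tensor as _t

            if not _t._GRAD_ENABLED:  # fused inference path
                scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
                return Tensor(x.data * scale + (self.beta.data - self.running_mean * scale))
            xhat = (x - Tensor(self.running_mean)) / (
                Tensor(self.running_var + self.eps) ** 0.5
            )
        return self.gamma * xhat + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2x()


class AvgPool2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class MaxPool2x(Module):
    """2×2 max pooling, stride 2 (used by the VGG backbones)."""

    def forward(self, x: Tensor) -> Tensor:
        from . import tensor as _t

        n, c, h, w = x.shape
        if not _t._GRAD_ENABLED:
            return Tensor(x.data.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5)))
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        # subgradient routed to the first max in each window (one-hot select)
        hot = np.zeros_like(xr.data)
        idx = np.argmax(xr.data, axis=-1)
        np.put_along_axis(hot, idx[..., None], 1.0, axis=-1)
        return (xr * Tensor(hot)).sum(axis=-1)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
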