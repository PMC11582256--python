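"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "LeakyReLU",
    "Tanh",
    "UpsampleNearest",
    "Flatten",
    "Sequential",
    "concat",
]


class Module:
    """Base class; parameters are discovered recursively by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_vector(self) -> np.ndarray:
        """Flat copy of all parameters (for change-detection and checkpoints)."""
        parts = [p.data.ravel().copy() for p in self.parameters()]
        return np.concatenate(parts) if parts else np.zeros(0, dtype=np.float32)

    def load_state_vector(self, vec: np.ndarray) -> None:
        offset = 0
        for p in self.parameters():
            n = p.data.size
            p.data = vec[offset : offset + n].reshape(p.data.shape).astype(np.float32)
            offset += n

    def __call__(self, *args):
        return self.forward(*args)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 zero_init: bool = False):
        fan_in = in_channels * kernel_size * kernel_size
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.standard_normal((in_features, out_features)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class UpsampleNearest(Module):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest(self.factor)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
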