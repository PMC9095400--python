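"""Parameterised layers built on the autodiff tape."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "PReLU", "Sequential"]


class Module:
    """Base class: recursive parameter discovery and train/eval plumbing."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter arrays in a stable order (for (de)serialisation)."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=p.data.dtype)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """3x3 (by default) convolution with He fan-in initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size))
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class PReLU(Module):
    """Parametric ReLU with learnable negative-branch slope.

    One slope per channel by default; ``shared=True`` uses a single slope
    for all channels. Slopes start at 0.25.
    """

    def __init__(self, channels: int, shared: bool = False, init: float = 0.25):
        n = 1 if shared else channels
        self.channels = channels
        self.shared = shared
        self.slope = Tensor(np.full(n, init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
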