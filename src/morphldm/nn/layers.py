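"""Neural-network building blocks on top of the autograd tensor.

Modules hold parameters as ``Tensor`` objects with ``requires_grad=True``
and expose them through :meth:`Module.parameters`. Initialisation draws
from an explicit ``numpy.random.Generator`` so every network is exactly
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from .functional import conv3d, upsample_nearest

__all__ = ["Module", "Parameter", "Linear", "Conv3d", "UpConv3d",
           "GroupNorm", "Sequential", "LeakyReLU", "ReLU", "Sigmoid", "Tanh"]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    """k×k×k convolution, isotropic stride/padding, He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 zero_init: bool = False):
        if padding is None:
            padding = k // 2
        fan_in = c_in * k ** 3
        if zero_init:
            w = np.zeros((c_out, c_in, k, k, k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class UpConv3d(Module):
    """Nearest-neighbour ×2 upsampling followed by a convolution."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.conv = Conv3d(c_in, c_out, k, rng, stride=1, zero_init=zero_init)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest(x, 2))


class GroupNorm(Module):
    """Group normalisation over (channels/groups × spatial) statistics."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        groups = min(groups, channels)
        while channels % groups:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.groups
        xg = x.reshape(N, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        norm = centered * ((var + self.eps) ** -0.5)
        norm = norm.reshape((N, C) + spatial)
        shape = (1, C) + (1,) * len(spatial)
        return norm * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
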