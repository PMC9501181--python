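"""Neural-network building blocks on top of :mod:`irisseg.autodiff`.

Modules follow the familiar container pattern: parameters and sub-modules
are discovered by attribute scan, ``state_dict`` round-trips through plain
ndarrays, and an :class:`Adam` optimizer updates parameters in place.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Linear", "Conv2d", "ConvTranspose2d", "LayerNorm", "BatchNorm2d",
    "ReLU", "ReLU6", "GELU", "Sigmoid", "Adam",
    "trunc_normal_", "DimensionError",
]


class DimensionError(ValueError):
    """An input's shape is incompatible with a layer or the architecture."""


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02,
                  dtype=np.float32) -> np.ndarray:
    """Normal(0, std) clipped to two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(dtype)


class Module:
    """Base container; sub-modules/parameters are plain attributes."""

    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization ---------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: np.asarray(v).copy() for name, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise DimensionError(
                    f"checkpoint shape mismatch for {name}: "
                    f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)
        for name, _ in self.named_buffers():
            if name in state:
                obj, attr = self, name
                while "." in attr:
                    head, attr = attr.split(".", 1)
                    obj = getattr(obj, head)
                setattr(obj, attr, np.asarray(state[name]))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._n = len(tuple(mods))

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, str(i % self._n if i < 0 else i))

    def __len__(self):
        return self._n


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal_(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[0]:
            raise DimensionError(
                f"Linear expected {self.weight.shape[0]} input features, "
                f"got {x.shape[-1]}")
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels // groups, k, k))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        self.in_channels = in_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise DimensionError(
                f"Conv2d expected {self.in_channels} input channels, got {x.shape[1]}")
        return ad.conv2d(x, self.weight, self.bias, self.stride,
                         self.padding, self.dilation, self.groups)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution that exactly doubles H and W.

    Kernel 4 / padding 1 (the default) tiles the output uniformly; kernel 3
    uses output padding 1 to reach the same doubled size.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 4,
                 bias: bool = True):
        super().__init__()
        if kernel_size not in (3, 4):
            raise ValueError("kernel_size must be 3 or 4")
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(in_channels, out_channels, k, k))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.in_channels = in_channels
        self.output_padding = 1 if k == 3 else 0

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise DimensionError(
                f"ConvTranspose2d expected {self.in_channels} input channels, "
                f"got {x.shape[1]}")
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=2,
                                   padding=1,
                                   output_padding=self.output_padding)


class LayerNorm(Module):
    """Normalization over the last axis, eps 1e-5."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalization on NCHW maps with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1).astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1).astype(np.float32))
            return xc * ((var + self.eps) ** -0.5) * w + b
        rm = Tensor(self.running_mean.reshape(1, -1, 1, 1).astype(x.dtype))
        rv = self.running_var.reshape(1, -1, 1, 1).astype(x.dtype)
        return (x - rm) * Tensor((rv + self.eps) ** -0.5) * w + b


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return ad.relu6(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class ConvBNAct(Module):
    """Conv2d -> BatchNorm2d -> optional ReLU6 (bias folded into the norm)."""

    def __init__(self, cin, cout, k, rng, stride=1, padding=0, dilation=1,
                 groups=1, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=padding,
                           dilation=dilation, groups=groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return ad.relu6(y) if self.act else y


# ----------------------------------------------------------------------
# optimizer
# ----------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
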