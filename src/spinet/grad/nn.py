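"""Layers, parameter containers and the Adam optimizer for the NumPy autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv2d, dwconv1d, lin2d

__all__ = [
    "Parameter", "Module", "Sequential", "Identity", "Conv2d", "DepthwiseConv1d",
    "GroupNorm", "ReLU", "Sigmoid", "Adam", "bilinear_matrix", "adaptive_avg_matrix",
    "upsample_bilinear", "adaptive_avg_pool",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        std = math.sqrt(2.0 / fan_in)          # He initialization for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std, size=(out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class DepthwiseConv1d(Module):
    """Per-channel 1-D convolution with 'same' padding, used on strip profiles."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / kernel_size)
        self.weight = Parameter(rng.normal(0.0, std, size=(channels, kernel_size)))
        self.bias = Parameter(np.zeros(channels))
        self.channels = channels

    def forward(self, x):
        return dwconv1d(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalization over (channels/groups, H, W) per sample; batch-size independent."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        g = math.gcd(num_groups, channels)      # always a valid divisor
        self.groups = g
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        shape = x.shape                          # (B, C, ...) any spatial rank
        B, C = shape[0], shape[1]
        if C != self.channels:
            raise ValueError(f"GroupNorm expects {self.channels} channels, got {C}")
        xg = x.reshape(B, self.groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        xn = xn.reshape(shape)
        pshape = (1, C) + (1,) * (len(shape) - 2)
        return xn * self.weight.reshape(pshape) + self.bias.reshape(pshape)


# -- spatial resampling ----------------------------------------------------

def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix with half-pixel centers and edge clamping."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        s = (i + 0.5) * n_in / n_out - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        lo = int(math.floor(s))
        hi = min(lo + 1, n_in - 1)
        t = s - lo
        A[i, lo] += 1.0 - t
        A[i, hi] += t
    return A


def adaptive_avg_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Averaging matrix mapping n_in samples onto n_out adaptive bins."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)       # ceil
        A[i, lo:hi] = 1.0 / (hi - lo)
    return A


def upsample_bilinear(x, out_h: int, out_w: int):
    _, _, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    return lin2d(x, bilinear_matrix(h, out_h), bilinear_matrix(w, out_w))


def adaptive_avg_pool(x, grid_h: int, grid_w: int):
    _, _, h, w = x.shape
    return lin2d(x, adaptive_avg_matrix(h, grid_h), adaptive_avg_matrix(w, grid_w))


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
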