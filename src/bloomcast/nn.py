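"""Neural-network layers and the Adam optimizer on top of :mod:`bloomcast.autodiff`.

Layers mirror the usual deep-learning vocabulary: ``Conv2d``,
``ConvTranspose2d``, ``BatchNorm2d``, ``Linear``, ``Dropout``.  Weights are
initialised from a truncated normal (sigma = 0.02, resampled beyond two
sigma), the conditional-GAN convention, from an explicit ``numpy`` RNG so
builds are reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Linear",
    "Dropout", "Adam", "truncated_normal",
]


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples with |x| > 2*std redrawn."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


class Module:
    """Minimal container with parameter traversal and train/eval modes."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        return self._buffers[name]

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _pair_padding(padding) -> tuple:
    """Normalise padding to (top, bottom, left, right)."""
    if isinstance(padding, int):
        return (padding,) * 4
    if len(padding) == 2:
        return (padding[0], padding[0], padding[1], padding[1])
    return tuple(padding)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding=0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = _pair_padding(padding)
        k = kernel_size
        self.weight = self.register_parameter(
            "weight", truncated_normal(rng, (out_channels, in_channels, k, k)))
        self.bias = (self.register_parameter("bias", np.zeros(out_channels, np.float32))
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 2, padding=1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = _pair_padding(padding)
        k = kernel_size
        self.weight = self.register_parameter(
            "weight", truncated_normal(rng, (in_channels, out_channels, k, k)))
        self.bias = (self.register_parameter("bias", np.zeros(out_channels, np.float32))
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    In training mode batch statistics are used and running statistics
    updated; in eval mode the running statistics are used.  With scale 1,
    offset 0 and frozen running stats (mean 0, var 1) in eval mode the layer
    is an identity passthrough, which the architecture oracles exploit.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = self.register_parameter("weight", np.ones(num_features, np.float32))
        self.bias = self.register_parameter("bias", np.zeros(num_features, np.float32))
        self.running_mean = self.register_buffer("running_mean",
                                                 np.zeros(num_features, np.float32))
        self.running_var = self.register_buffer("running_var",
                                                np.ones(num_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) * (x - mean)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mean.data.reshape(-1)
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var.data.reshape(-1)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mean) * (var + self.eps).power(-0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = self.register_parameter(
            "weight", truncated_normal(rng, (in_features, out_features)))
        self.bias = (self.register_parameter("bias", np.zeros(out_features, np.float32))
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout driven by an explicit RNG for reproducibility."""

    def __init__(self, rate: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of tensors."""

    def __init__(self, params, lr: float = 0.001, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
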