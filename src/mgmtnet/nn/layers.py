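"""Neural-network layers built on the autograd engine.

All layers follow the NCHW convention.  Weight initialization is He-normal
(variance 2/fan_in), which suits the ReLU-family activations used
throughout the pipeline.  Modules are deterministic given the
``numpy.random.Generator`` supplied at construction.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, conv2d, leaky_relu, max_pool2d, relu, sigmoid,
                       sqrt, upsample_nearest2d)

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "GroupNorm",
    "BatchNorm2d",
    "MaxPool2d",
    "UpsampleNearest2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int,
              dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
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
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

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
            p.grad = None

    def n_parameters(self) -> int:
        """Total count of trainable scalars (weights, biases, norm affine)."""
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data.copy()
            elif isinstance(v, Module):
                out.update({f"{name}.{k}": a for k, a in v.state_dict().items()})
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update({f"{name}.{i}.{k}": a
                                    for k, a in item.state_dict().items()})
            elif isinstance(v, np.ndarray):  # buffers (running stats)
                out[name] = v.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for key, arr in state.items():
            obj, attr = self._resolve(key)
            cur = getattr(obj, attr)
            if isinstance(cur, Tensor):
                if cur.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                cur.data = arr.astype(cur.data.dtype).copy()
            else:
                setattr(obj, attr, arr.copy())

    def _resolve(self, key: str):
        parts = key.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(he_normal(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization: batch-size independent, robust at batch size 8."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            num_groups = int(np.gcd(num_groups, channels))
        self.groups, self.eps = num_groups, eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, (C // g) * H * W)
        m = xg.mean(axis=2, keepdims=True)
        d = xg - m
        v = (d * d).mean(axis=2, keepdims=True)
        xn = d / sqrt(v + self.eps)
        return xn.reshape(N, C, H, W) * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32),
                           requires_grad=True)
        # running statistics are buffers, not trainable parameters
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            d = x - m
            v = (d * d).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v.data)
            xn = d / sqrt(v + self.eps)
        else:
            xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xn * self.gamma + self.beta


class MaxPool2d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.k)


class UpsampleNearest2d(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2d(x, self.factor)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.3):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  The mask generator is
    supplied per-forward for reproducibility."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        rng = rng or np.random.default_rng(0)
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
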