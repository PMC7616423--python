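"""Layers built on the autodiff core: modules, convolutions, normalization."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avg_pool1d, conv1d, dropout, max_pool1d

PARAM_DTYPE = np.float32   # model parameters and activations run in single precision

__all__ = ["Module", "Conv1d", "Dense", "TimeNorm", "Dropout", "MaxPool1d", "AvgPool1d"]


class Module:
    """Minimal module: recursive parameter collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]):
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    """Same-padded grouped 1-D convolution along the time axis, He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 groups: int = 1, bias: bool = True):
        fan_in = (c_in // groups) * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(c_out, c_in // groups, kernel))
                             .astype(PARAM_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=PARAM_DTYPE), requires_grad=True) \
            if bias else None
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, groups=self.groups)


class Dense(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator, bias: bool = True):
        std = np.sqrt(2.0 / f_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(f_in, f_out)).astype(PARAM_DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(f_out, dtype=PARAM_DTYPE), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class TimeNorm(Module):
    """Per-channel normalization over the time axis of each segment.

    Each (segment, channel) trace is standardized over its time samples and
    re-scaled by a learnable per-channel affine; independent of the batch, so
    inference behaves identically at any batch size.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1), dtype=PARAM_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1), dtype=PARAM_DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=2, keepdims=True)
        centered = x - m
        var = (centered ** 2.0).mean(axis=2, keepdims=True)
        y = centered * ((var + self.eps) ** -0.5)
        return y * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class MaxPool1d(Module):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.size)


class AvgPool1d(Module):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool1d(x, self.size)
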