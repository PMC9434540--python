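"""Neural-network layers built on the autograd tensor."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: children registered by attribute assignment."""

    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                seen.add(id(v))
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)
    return Tensor(w, requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = _he_init(rng, (out_ch, fan_in), fan_in)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H < self.kernel or W < self.kernel:
            raise ValueError(f"input {H}x{W} smaller than kernel {self.kernel}")
        Ho = (H + 2 * self.pad - self.kernel) // self.stride + 1
        Wo = (W + 2 * self.pad - self.kernel) // self.stride + 1
        cols = T.unfold(x, self.kernel, self.stride, self.pad)      # (B, Ckk, L)
        out = T.matmul(self.weight, cols)                            # (B, out_ch, L)
        out = T.reshape(out, (B, self.out_ch, Ho, Wo))
        return T.add(out, T.reshape(self.bias, (1, self.out_ch, 1, 1)))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.weight), self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2d(x, self.kernel)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.reshape(x, (x.shape[0], -1))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
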