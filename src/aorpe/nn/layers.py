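"""Layers and parameter containers for the NumPy network engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "DTYPE"]

DTYPE = np.float32


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _params_of(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _params_of(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _params_of(item)


class Conv2d(Module):
    """3x3-by-default convolution with He-style initialisation."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(
            (rng.standard_normal((cout, cin, k, k)) * scale).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / din)
        self.weight = Tensor(
            (rng.standard_normal((din, dout)) * scale).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(dout, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
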