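"""Neural-network layers and optimizer on top of :mod:`modrepair.autodiff`.

Layers follow the usual train/eval convention: batch normalization uses
batch statistics (and updates running statistics) in training mode and the
stored running statistics in evaluation mode, so evaluation-mode forward
passes are deterministic and per-sample independent.

Parameter initialization is fan-in-scaled uniform, drawn from a
``numpy.random.Generator`` passed to each layer so a single seed fully
determines the network.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, batchnorm

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery, mode switching, state (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All arrays needed to restore the module (parameters + buffers)."""
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.named_state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{i}."))
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{k}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in list(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.asarray(state[key], dtype=DTYPE).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(state[key], dtype=v.dtype).reshape(v.shape))
            elif isinstance(v, Module):
                v.load_state(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{k}.")

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
        return sum(p.data.size for p in self.parameters())


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_fan_in_uniform(rng, (d_in, d_out), d_in))
        self.bias = Parameter(_fan_in_uniform(rng, (d_out,), d_in))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution, stride 1, zero same-padding, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel
        self.weight = Parameter(_fan_in_uniform(rng, (c_out, c_in, kernel), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (c_out,), fan_in))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d_same(self.weight, self.bias)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, T) or (N, C) inputs, per channel C."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
            return batchnorm(x, self.gamma, self.beta, axes, eps=self.eps,
                             stats=(mu, var), stats_are_batch=True)
        return batchnorm(x, self.gamma, self.beta, axes, eps=self.eps,
                         stats=(self.running_mean, self.running_var),
                         stats_are_batch=False)


class Adam:
    """Adam with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
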