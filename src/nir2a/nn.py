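"""Neural-network layers and the Adam optimizer on top of :mod:`nir2a.autodiff`.

Layers hold their parameters as :class:`~nir2a.autodiff.Tensor` objects;
initialisation is driven entirely by a caller-supplied numpy Generator so a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
                        yield from v.modules()

    def named_parameters(self, prefix: str = ""):
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(name + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpoint plumbing ------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for key, value in self.__dict__.items():
            if isinstance(value, Module):
                for k, v in value.state_dict().items():
                    state[f"{key}.{k}"] = v
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        for k, vv in v.state_dict().items():
                            state[f"{key}.{i}.{k}"] = vv
            elif isinstance(value, np.ndarray):  # running statistics
                state[key] = value.copy()
        return state

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for key, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                np.copyto(value, state[key])
        for key, value in self.__dict__.items():
            if isinstance(value, Module):
                sub = {k[len(key) + 1:]: v for k, v in state.items()
                       if k.startswith(key + ".")}
                value.load_state_dict(sub)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        pre = f"{key}.{i}."
                        sub = {k[len(pre):]: vv for k, vv in state.items()
                               if k.startswith(pre)}
                        v.load_state_dict(sub)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = Tensor(_he(rng, (c_out, c_in, k, k), c_in * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)

    __call__ = forward


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        return ad.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)

    __call__ = forward


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        super().__init__()
        self.weight = Tensor(_he(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, np.float32), requires_grad=True)

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)

    __call__ = forward


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(d, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, np.float32), requires_grad=True)

    def forward(self, x):
        return ad.layernorm(x, self.gamma, self.beta, self.eps)

    __call__ = forward


class Adam:
    """Standard Adam with bias correction; state kept per parameter."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
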