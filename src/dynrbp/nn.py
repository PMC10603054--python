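"""Neural-network layers and optimization on top of :mod:`dynrbp.autograd`.

Conventions follow the usual deep-learning layer semantics: Conv1d operates
on (N, C, L) arrays, BatchNorm1d keeps running statistics with momentum 0.1
for evaluation mode, and all weights use Kaiming (He) initialization drawn
from a caller-supplied :class:`numpy.random.Generator` so construction is
fully reproducible.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


def kaiming_normal(rng: np.random.Generator, shape: Tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterator[Tuple[str, object]]:
        """Named Parameter/Module children, flattening nested lists/tuples."""

        def walk(name, value):
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            yield from walk(name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, value in self._children():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def _buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray, "Module", str]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield f"{prefix}{name}", value, self, name
        for name, value in self._children():
            if isinstance(value, Module):
                yield from value._buffers(f"{prefix}{name}.")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr, _, _ in self._buffers():
            state[name] = arr.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (owner, attr) for name, _, owner, attr in self._buffers()}
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {arr.shape}")
                params[name].data = arr.astype(DTYPE).copy()
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, arr.copy())
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(kaiming_normal(rng, (in_features, out_features),
                                               in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    """1-D convolution, (N, C_in, L) -> (N, C_out, L_out), bias-free by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 bias: bool = False):
        super().__init__()
        if padding is None:
            if kernel_size % 2 == 0:
                raise ValueError("same-padding requires an odd kernel size")
            padding = (kernel_size - 1) // 2
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x.conv1d(self.weight, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1)
        return out


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L); running stats for evaluation."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = x.batchnorm_train(self.gamma, self.beta,
                                               eps=self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        # evaluation: affine transform with frozen statistics
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        if x.requires_grad:
            inv = Tensor(inv_std.reshape(1, -1, 1))
            mean = Tensor(self.running_mean.reshape(1, -1, 1))
            return ((x - mean) * inv * self.gamma.reshape(1, -1, 1)
                    + self.beta.reshape(1, -1, 1))
        scale = (self.gamma.data * inv_std).reshape(1, -1, 1)
        shift = (self.beta.data - self.gamma.data * self.running_mean
                 * inv_std).reshape(1, -1, 1)
        return Tensor(x.data * scale + shift)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, (num_embeddings, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids)]


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with decoupled-from-loss L2 weight decay added to the gradient."""

    def __init__(self, params: List[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
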