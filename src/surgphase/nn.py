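"""Neural-network layers and parameter management on top of :mod:`autodiff`.

Provides the building blocks shared by the frame encoder and the temporal
model: convolutions, batch normalisation, linear layers, residual blocks and
an SGD-with-momentum optimiser.  Weight initialisation draws from an explicit
``numpy.random.Generator`` so that model construction is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


# Model weights are kept in single precision: at the problem sizes this
# package targets the ~2x throughput matters and the precision does not.
# The autodiff engine itself is dtype-agnostic (float64 by default).
DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state (de)serialisation."""

    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state --------------------------------------------------------------
    def _buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child._buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + name: b.copy() for name, b in self._buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self._buffers())
        for key, val in state.items():
            if key.startswith("buf:"):
                buf = bufs[key[4:]]
                np.copyto(buf, val)
            else:
                p = params[key]
                if p.data.shape != val.shape:
                    raise ValueError(f"shape mismatch loading {key}: "
                                     f"{p.data.shape} vs {val.shape}")
                p.data = np.asarray(val, dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _rng(rng) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng()


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=False, rng=None):
        super().__init__()
        r = _rng(rng)
        kh = kw = kernel
        fan_out = out_ch * kh * kw
        std = np.sqrt(2.0 / fan_out)  # He init, fan-out mode
        self.weight = Parameter(r.normal(0.0, std, (out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv1dCausal(Module):
    def __init__(self, in_ch, out_ch, kernel, dilation=1, bias=True, rng=None):
        super().__init__()
        r = _rng(rng)
        std = np.sqrt(2.0 / (out_ch * kernel))
        self.weight = Parameter(r.normal(0.0, std, (out_ch, in_ch, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.dilation = dilation

    def forward(self, x):
        return ad.conv1d_causal(x, self.weight, self.bias, self.dilation)


class BatchNorm2d(Module):
    """Per-channel normalisation; batch statistics in training, running in eval."""

    def __init__(self, num_ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=DTYPE)
        self.running_var = np.ones(num_ch, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        if self.training:
            mu = ad.mean(x, axis=(0, 2, 3), keepdims=True)
            var = ad.mean((x - mu) ** 2.0, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += m * (var.data.reshape(-1) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ad.power(var + self.eps, -0.5)
        g = ad.reshape(self.gamma, (1, -1, 1, 1))
        b = ad.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        r = _rng(rng)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(r.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(r.uniform(-bound, bound, out_features))

    def forward(self, x):
        return ad.matmul(x, ad.transpose(self.weight, (1, 0))) + self.bias


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ad.maxpool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# residual blocks (standard basic / bottleneck designs)
# ---------------------------------------------------------------------------

class BasicBlock(Module):
    expansion = 1

    def __init__(self, in_ch, ch, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(in_ch, ch, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(ch)
        out_ch = ch * self.expansion
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride, rng=rng),
                                   BatchNorm2d(out_ch))
        else:
            self.down = None

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = ad.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return ad.relu(out + identity)


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch, ch, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(in_ch, ch, 1, rng=rng)
        self.bn1 = BatchNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, stride, 1, rng=rng)
        self.bn2 = BatchNorm2d(ch)
        self.conv3 = Conv2d(ch, ch * self.expansion, 1, rng=rng)
        self.bn3 = BatchNorm2d(ch * self.expansion)
        out_ch = ch * self.expansion
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride, rng=rng),
                                   BatchNorm2d(out_ch))
        else:
            self.down = None

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = ad.relu(self.bn1(self.conv1(x)))
        out = ad.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return ad.relu(out + identity)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            new = p.data - float(self.lr) * v
            p.data = new.astype(p.data.dtype, copy=False)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
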