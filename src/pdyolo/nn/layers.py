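"""Module system and standard layers built on the autodiff core."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval, state dict."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- mode / grads ---------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buf::" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buf::"):
                bufs[k[5:]][...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel,
                 stride: int = 1, padding=None, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if padding is None:
            padding = (kh // 2, kw // 2)
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, (kh, kw)
        fan_in = in_channels // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        rng = _init_rng()
        self.weight = Parameter(
            rng.uniform(-bound, bound,
                        (out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        rng = _init_rng()
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    # YOLO-family convention: momentum 0.03, eps 1e-3
    def __init__(self, channels: int, momentum: float = 0.03, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum,
                              self.eps)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(
                f"GroupNorm: channels={channels} not divisible by groups={groups}; "
                f"choose a smaller group count that divides the channels")
        self.groups, self.eps = groups, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        return F.group_norm(x, self.weight, self.bias, self.groups, self.eps)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


# ---------------------------------------------------------------------------
# init seeding: builds are reproducible given pdyolo.nn.seed_init(seed)
# ---------------------------------------------------------------------------

_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reset the weight-init stream; two builds after the same call are identical."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def _init_rng():
    return _INIT_RNG


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum and decoupled-from-norm weight decay.

    Weight decay is applied only to parameters flagged (conv/linear weights);
    biases and norm affine terms are excluded, following common detector
    training practice.
    """

    def __init__(self, named_params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.groups = []
        for name, p in named_params:
            decay = weight_decay if (name.endswith("weight") and p.data.ndim > 1) else 0.0
            self.groups.append((p, decay, np.zeros_like(p.data)))
        self.lr, self.momentum = lr, momentum

    def step(self):
        for p, decay, buf in self.groups:
            if p.grad is None:
                continue
            g = p.grad
            if decay:
                g = g + decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self):
        for p, _, _ in self.groups:
            p.grad = None
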