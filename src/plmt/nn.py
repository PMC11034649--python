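"""Neural-network building blocks and SGD optimizer on the autodiff engine.

Provides 2D convolution, batch normalization, the conv-BN-ReLU double block
used by the encoder-decoder backbone, and SGD with momentum, weight decay
and per-step learning rates. Parameters are named hierarchically
(``enc0.block.conv1.weight``) so two networks built from the same
architecture have congruent state dicts — the property the exponential
moving average update relies on.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ._autodiff import Tensor, batchnorm2d

BN_EPS = 1e-5
BN_MOMENTUM = 0.1  # fraction of the batch statistic folded into running stats


class Module:
    """Base class: children discovered from instance attributes, in order."""

    def _children(self):
        for name, val in self.__dict__.items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in self.__dict__.items():
            if isinstance(val, Tensor):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name, val in self.__dict__.items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[name] = b.copy()
        return out

    def load_state_dict(self, state: "OrderedDict[str, np.ndarray]") -> None:
        params = dict(self.named_parameters())
        holders = {}
        for name, _ in self.named_buffers():
            holders[name] = self._locate_buffer(name)
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = arr.astype(np.float32).copy()
            elif name in holders:
                obj, attr = holders[name]
                if getattr(obj, attr).shape != arr.shape:
                    raise ValueError(f"shape mismatch for buffer {name!r}")
                setattr(obj, attr, arr.astype(np.float32).copy())
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _locate_buffer(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        return obj, parts[-1]

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag
            if not flag:
                p.grad = None
                p._parents = ()
                p._backward = None


class Conv2d(Module):
    """Stride-1 same-padding convolution with He-normal initialization."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        self.ksize = ksize
        fan_in = cin * ksize * ksize
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(cout, fan_in)).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.ksize)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        shape = (1, channels, 1, 1)
        self.gamma = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(shape, dtype=np.float32)
        self.running_var = np.ones(shape, dtype=np.float32)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            out, mu, var = batchnorm2d(x, self.gamma, self.beta, BN_EPS)
            self.running_mean += BN_MOMENTUM * (mu - self.running_mean)
            self.running_var += BN_MOMENTUM * (var - self.running_var)
            return out
        xhat = (x - Tensor(self.running_mean)) * \
            Tensor((self.running_var + BN_EPS) ** -0.5)
        return xhat * self.gamma + self.beta


class DoubleConv(Module):
    """conv-BN-ReLU applied twice, the per-stage block of the backbone."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        x = self.bn1(self.conv1(x), train).relu()
        return self.bn2(self.conv2(x), train).relu()


class SGD:
    """SGD with momentum and decoupled-from-nothing (classic L2) weight decay.

    ``v <- momentum*v + grad + wd*w ; w <- w - lr*v`` with per-step ``lr``.
    Parameters listed in ``no_decay`` skip the L2 term.
    """

    def __init__(self, params: list[Tensor], momentum: float = 0.9,
                 weight_decay: float = 0.0, no_decay: tuple = ()):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.no_decay = set(id(p) for p in no_decay)
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and id(p) not in self.no_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
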