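"""Layer/module abstractions on top of the autodiff tensor.

Modules hold named :class:`Parameter` tensors plus non-trainable buffers
(batch-norm running statistics). ``state_dict``/``load_state_dict`` give an
exact, ordered snapshot of both, which is what checkpointing round-trips.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Parameter", "Module", "Conv2d", "BatchNorm2d", "Linear",
    "Dropout", "Sequential", "concat",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def __init__(self):
        self.training = True

    def modules(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield val
            elif isinstance(val, Module):
                yield from val.parameters()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def _named_entries(self, prefix=""):
        for name, val in vars(self).items():
            if name == "training":
                continue
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, np.ndarray):
                yield key, val
            elif isinstance(val, Module):
                yield from val._named_entries(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_entries(prefix=f"{key}.{i}.")

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out = OrderedDict()
        for key, val in self._named_entries():
            out[key] = (val.data if isinstance(val, Tensor) else val).copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        entries = dict(self._named_entries())
        missing = set(entries) - set(state)
        extra = set(state) - set(entries)
        if missing or extra:
            raise KeyError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for key, val in entries.items():
            src = np.asarray(state[key], dtype=np.float32)
            if isinstance(val, Tensor):
                if val.data.shape != src.shape:
                    raise ValueError(f"shape mismatch for {key}")
                val.data[...] = src
            else:
                val[...] = src

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_ch, np.float32))
        self.beta = Parameter(np.zeros(num_ch, np.float32))
        self.running_mean = np.zeros(num_ch, np.float32)
        self.running_var = np.ones(num_ch, np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return x.batchnorm(self.gamma, self.beta, self.running_mean,
                           self.running_var, training=self.training,
                           momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode. Mask drawn from its own rng
    stream so forward passes stay reproducible under a fixed seed."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
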