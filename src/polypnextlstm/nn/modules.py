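"""Layer abstractions over the autodiff core (a torch.nn-like surface)."""

from __future__ import annotations

import numpy as np

from .core import (
    Parameter,
    Tensor,
    batch_norm2d,
    concat,
    conv2d,
    conv_transpose2d,
    layer_norm_cf,
)

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "LayerNorm2d",
    "BatchNorm2d",
    "GELU",
    "ReLU",
    "ConvLSTMCell",
    "count_parameters",
]


class Module:
    """Base class: parameter/buffer registry, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    # child discovery follows attribute insertion order, so parameter
    # ordering (and hence seeded initialization) is deterministic
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

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

    def state_dict(self):
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name]).astype(p.data.dtype).reshape(p.shape)
        for name, b in self.named_buffers():
            b[...] = np.asarray(d[name]).reshape(b.shape)

    def initialize(self, rng: np.random.Generator):
        """Seeded weight init, depth-first in registration order."""
        self.reset_parameters(rng)
        for _, child in self._children():
            child.initialize(rng)
        return self

    def reset_parameters(self, rng: np.random.Generator):
        pass

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _trunc_normal(rng, shape, std):
    # resample outside +-2 std (ConvNeXt convention)
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 init: str = "he"):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        self.init = init
        self.fan_in = (cin // groups) * kernel * kernel
        self.weight = Parameter(
            np.zeros((cout, cin // groups, kernel, kernel), dtype=np.float32)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def reset_parameters(self, rng):
        if self.init == "trunc":
            w = _trunc_normal(rng, self.weight.shape, 0.02)
        else:
            w = rng.standard_normal(self.weight.shape) * np.sqrt(2.0 / self.fan_in)
        self.weight.data = w.astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros_like(self.bias.data)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    """Stride-matched transposed convolution (kernel == stride)."""

    def __init__(self, cin: int, cout: int, kernel: int = 2, stride: int = 2):
        super().__init__()
        self.stride = stride
        self.fan_in = cin * kernel * kernel
        self.weight = Parameter(
            np.zeros((cin, cout, kernel, kernel), dtype=np.float32)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def reset_parameters(self, rng):
        w = rng.standard_normal(self.weight.shape) * np.sqrt(2.0 / self.fan_in)
        self.weight.data = w.astype(np.float32)
        self.bias.data = np.zeros_like(self.bias.data)

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class LayerNorm2d(Module):
    """Layer norm over channels of an NCHW map."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def reset_parameters(self, rng):
        self.weight.data = np.ones_like(self.weight.data)
        self.bias.data = np.zeros_like(self.bias.data)

    def forward(self, x):
        return layer_norm_cf(x, self.weight, self.bias, self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffer_names = ["running_mean", "running_var"]

    def reset_parameters(self, rng):
        self.weight.data = np.ones_like(self.weight.data)
        self.bias.data = np.zeros_like(self.bias.data)
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x):
        return batch_norm2d(x, self.weight, self.bias,
                            self.running_mean, self.running_var,
                            self.training, self.momentum, self.eps)


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class ConvLSTMCell(Module):
    """Convolutional LSTM cell: all four gates from one 3x3 convolution
    over the channel concatenation of input and hidden state."""

    def __init__(self, cin: int, hidden: int, kernel: int = 3, padding: int = 1):
        super().__init__()
        self.hidden = hidden
        self.gates = Conv2d(cin + hidden, 4 * hidden, kernel, padding=padding)

    def forward(self, x: Tensor, h: Tensor, c: Tensor):
        z = self.gates(concat([x, h], axis=1))
        i = z.narrow(1, 0, self.hidden).sigmoid()
        f = z.narrow(1, self.hidden, self.hidden).sigmoid()
        o = z.narrow(1, 2 * self.hidden, self.hidden).sigmoid()
        g = z.narrow(1, 3 * self.hidden, self.hidden).tanh()
        c_next = f * c + i * g
        h_next = o * c_next.tanh()
        return h_next, c_next

    def init_state(self, batch: int, h: int, w: int):
        shape = (batch, self.hidden, h, w)
        return (Tensor(np.zeros(shape, dtype=np.float32)),
                Tensor(np.zeros(shape, dtype=np.float32)))


def count_parameters(module: Module) -> int:
    """Number of trainable scalar parameters in a module (0 if none)."""
    return int(sum(p.data.size for p in module.parameters()))
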