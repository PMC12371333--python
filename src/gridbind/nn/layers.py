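"""Parameterised layers and the Module container protocol."""

from __future__ import annotations

import numpy as np

from ..errors import GridbindError
from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Lightweight container: tracks parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise GridbindError(f"state dict does not match model parameters: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise GridbindError(f"parameter {name}: expected shape {p.data.shape}, "
                                    f"got {state[name].shape}")
            p.data = state[name].astype(p.data.dtype, copy=True)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise GridbindError(f"Linear expected {self.in_features} features, got {x.shape[-1]}")
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_edge: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dtype=np.float32, bias: bool = True):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_edge, self.stride, self.padding = kernel_edge, stride, padding
        fan_in = in_channels * kernel_edge ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, scale, (out_channels, in_channels, kernel_edge, kernel_edge, kernel_edge)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise GridbindError(f"Conv3d expected {self.in_channels} channels, got {x.shape[1]}")
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise GridbindError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return ad.mul(x, mask.astype(x.dtype))


class LSTMCell(Module):
    """Vanilla LSTM cell with gate order (i, f, g, o) and no peepholes."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        scale = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Parameter(rng.uniform(-scale, scale, (input_size, 4 * hidden_size)).astype(dtype))
        self.w_hh = Parameter(rng.uniform(-scale, scale, (hidden_size, 4 * hidden_size)).astype(dtype))
        bias = np.zeros(4 * hidden_size, dtype=dtype)
        bias[hidden_size:2 * hidden_size] = 1.0  # forget gate starts open
        self.bias = Parameter(bias)

    def forward(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        hs = self.hidden_size
        z = ad.matmul(x, self.w_ih) + ad.matmul(h, self.w_hh) + self.bias
        i = ad.sigmoid(z[:, :hs])
        f = ad.sigmoid(z[:, hs:2 * hs])
        g = ad.tanh(z[:, 2 * hs:3 * hs])
        o = ad.sigmoid(z[:, 3 * hs:])
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def init_state(self, batch: int, dtype=np.float32) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.hidden_size), dtype=dtype)
        return Tensor(z.copy()), Tensor(z.copy())


class ConvLSTMCell(Module):
    """Convolutional LSTM cell: gate transforms are same-padded 3-D convolutions.

    Gates (order i, f, g, o)::

        i, f, o = sigmoid(conv(x) + conv(h) + b)
        g       = tanh(conv(x) + conv(h) + b)
        c_t     = f * c_{t-1} + i * g
        h_t     = o * tanh(c_t)

    No peephole connections; hidden and cell states keep the input's spatial
    shape.
    """

    def __init__(self, in_channels: int, hidden_channels: int, kernel_edge: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_edge % 2 == 0:
            raise GridbindError("ConvLSTM kernel edge must be odd (same padding)")
        self.in_channels, self.hidden_channels = in_channels, hidden_channels
        pad = kernel_edge // 2
        self.conv_x = Conv3d(in_channels, 4 * hidden_channels, kernel_edge, rng,
                             padding=pad, dtype=dtype, bias=True)
        self.conv_h = Conv3d(hidden_channels, 4 * hidden_channels, kernel_edge, rng,
                             padding=pad, dtype=dtype, bias=False)

    def forward(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape[2:] != h.shape[2:]:
            raise GridbindError(f"input spatial shape {x.shape[2:]} does not match "
                                f"state spatial shape {h.shape[2:]}")
        hc = self.hidden_channels
        z = self.conv_x(x) + self.conv_h(h)
        i = ad.sigmoid(z[:, :hc])
        f = ad.sigmoid(z[:, hc:2 * hc])
        g = ad.tanh(z[:, 2 * hc:3 * hc])
        o = ad.sigmoid(z[:, 3 * hc:])
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def init_state(self, batch: int, spatial: tuple, dtype=np.float32) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.hidden_channels) + tuple(spatial), dtype=dtype)
        return Tensor(z.copy()), Tensor(z.copy())
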