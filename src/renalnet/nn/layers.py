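"""Layer modules built on the autodiff engine.

Parameter conventions (these drive the exact trainable-parameter ledger):
convolution and dense layers carry a bias unless constructed with
``bias=False``; batch normalisation contributes two trainable parameters per
channel (scale and shift) — its running statistics are buffers, not
parameters.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d, maxpool2x2


class Module:
    """Base class: parameter discovery, train/eval mode, dtype conversion."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}.{key}" if prefix else key
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(name)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}[{i}]")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{name}[{i}]", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def to_dtype(self, dtype):
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for key, val in vars(m).items():
                if isinstance(val, np.ndarray):
                    setattr(m, key, val.astype(dtype))
        return self

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for key, val in vars(self).items():
            name = f"{prefix}.{key}" if prefix else key
            if isinstance(val, np.ndarray):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(name)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}[{i}]")

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buf::{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, b in self.named_buffers():
            key = f"buf::{name}"
            if key in state:
                b[...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution, 'same'-style padding chosen by the caller.

    Weights are He-normal initialised from the supplied generator so that
    model construction is reproducible from a single seed.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch // groups * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        self.stride, self.dilation, self.groups = stride, dilation, groups
        self.kernel = kernel
        # dilation-aware 'same' padding by default (pad = d*(k-1)/2 for odd k)
        self.padding = padding if padding is not None else dilation * (kernel - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"channel mismatch: expected {self.in_ch} input channels, got {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class DepthwiseConv2d(Conv2d):
    """3x3 depthwise convolution (one filter per channel)."""

    def __init__(self, channels: int, kernel: int = 3, stride: int = 1, dilation: int = 1,
                 bias: bool = True, rng=None):
        super().__init__(channels, channels, kernel=kernel, stride=stride,
                         dilation=dilation, groups=channels, bias=bias, rng=rng)


class Dense(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True) if bias else None
        self.in_f, self.out_f = in_f, out_f

    def forward(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm(Module):
    """Batch normalisation for NCHW maps or (N,C) vectors."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean, self.running_var,
                          training=self.training, momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class MaxPool2x2(Module):
    def forward(self, x):
        return maxpool2x2(x)


class GlobalAvgPool(Module):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x):
        return x.mean((2, 3))


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
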