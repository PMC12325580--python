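"""Multiple Channel Residual Transformation (MCRT) block and its squeeze-and-
excitation (SE) unit.

An MCRT stage keeps the channel width C and the spatial size fixed.  Three
parallel paths each apply a 3x3 'same' convolution, batch norm and ReLU,
re-calibrate channels with an SE gate at a path-specific excitation ratio
(2, 4, 8 for the reference model), and pass through a second batch norm.  The
block output is the element-wise sum of the input (identity connection) and
the three path outputs:

    out = x + Y~1 + Y~2 + Y~3

so a block whose weights are all zero is exactly the identity, and the input
Jacobian always contains an additive identity term — the property that makes
deep stacks of these blocks trainable.

Trainable-parameter algebra (used by the exact model ledger):

    SE unit at width C, ratio r:    2*C^2/r + C/r + C
    one conv path (excluding SE):   9*C^2 + 5*C      (conv w+b, two BNs)
    MCRT block at ratio set R:      27*C^2 + 15*C + sum_r SE(C, r)
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm, Conv2d, Dense, Module, Tensor


def se_param_count(C: int, r: int) -> int:
    """Trainable parameters of one SE unit: two biased dense layers C->C/r->C."""
    if C % r:
        raise ValueError(f"excitation ratio {r} does not divide channel width {C}")
    return 2 * C * C // r + C // r + C


def conv_path_param_count(C: int) -> int:
    """One MCRT path at width C, excluding its SE unit: conv 3x3 (9C^2 + C) + two BNs (4C)."""
    return 9 * C * C + 5 * C


def mcrt_param_count(C: int, ratios=(2, 4, 8)) -> int:
    return 3 * conv_path_param_count(C) + sum(se_param_count(C, r) for r in ratios)


class SEUnit(Module):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool to a C-vector.  Excite: bottleneck dense
    layer to C/r with ReLU, expansion back to C, logistic gate.  The gate is
    applied multiplicatively per channel, so every output channel is the
    corresponding input channel scaled by a factor in (0, 1).
    """

    def __init__(self, channels: int, ratio: int, rng=None):
        super().__init__()
        if channels % ratio or channels // ratio < 1:
            raise ValueError(
                f"reduced width C/r must be a positive integer; got C={channels}, r={ratio}")
        self.channels, self.ratio = channels, ratio
        self.fc1 = Dense(channels, channels // ratio, rng=rng)
        self.fc2 = Dense(channels // ratio, channels, rng=rng)

    def gate(self, s: Tensor) -> Tensor:
        """Excitation gate from a squeezed (N,C) descriptor."""
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, y: Tensor) -> Tensor:
        s = y.mean((2, 3))                      # squeeze
        g = self.gate(s)                        # (N,C) in (0,1)
        n, c = g.shape
        return y * g.reshape(n, c, 1, 1)


class ConvPath(Module):
    """One MCRT path: Conv3x3('same', bias) -> BN -> ReLU, plus a second BN
    applied after the SE gate (see :class:`MCRTBlock`)."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.channels = channels
        self.conv = Conv2d(channels, channels, kernel=3, stride=1, rng=rng)
        self.bn1 = BatchNorm(channels)
        self.bn2 = BatchNorm(channels)

    def forward(self, x: Tensor) -> Tensor:
        """Conv -> BN -> ReLU (the pre-SE part of the path)."""
        return self.bn1(self.conv(x)).relu()


class MCRTBlock(Module):
    """Three ConvPath+SE pairs summed with an identity connection."""

    def __init__(self, channels: int, ratios=(2, 4, 8), rng=None):
        super().__init__()
        self.channels = channels
        self.ratios = tuple(ratios)
        if len(self.ratios) != 3:
            raise ValueError("an MCRT block has exactly three paths")
        self.paths = [ConvPath(channels, rng=rng) for _ in self.ratios]
        self.se_units = [SEUnit(channels, r, rng=rng) for r in self.ratios]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"channel mismatch: expected {self.channels}, got {x.shape[1]}")
        out = x
        for path, se in zip(self.paths, self.se_units):
            y = path(x)
            y = se(y)
            y = path.bn2(y)
            if y.shape != x.shape:
                raise RuntimeError(f"path output shape {y.shape} disagrees with input {x.shape}")
            out = out + y
        return out

    def zero_(self):
        """Set every trainable parameter (incl. BN scales) to zero: the block
        then reduces exactly to the identity map."""
        for p in self.parameters():
            p.data[...] = 0.0
        return self


# ---------------------------------------------------------------------------
# Functional surface on single feature maps (H, W, C numpy arrays)
# ---------------------------------------------------------------------------

def _to_nchw(x: np.ndarray) -> Tensor:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected an H x W x C feature map, got shape {x.shape}")
    return Tensor(x.transpose(2, 0, 1)[None].astype(np.float64))


def _to_hwc(t: Tensor) -> np.ndarray:
    return t.data[0].transpose(1, 2, 0)


def conv_path_forward(x: np.ndarray, path: ConvPath) -> np.ndarray:
    """Run one path's conv -> BN -> ReLU on a single H x W x C map."""
    if x.shape[2] != path.channels:
        raise ValueError(f"channel mismatch: expected {path.channels} channels, got {x.shape[2]}")
    path.eval()
    return _to_hwc(path(_to_nchw(x)))


def se_squeeze(y: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of an H x W x C map -> length-C vector."""
    y = np.asarray(y)
    if y.ndim != 3:
        raise ValueError(f"expected an H x W x C feature map, got shape {y.shape}")
    return y.mean(axis=(0, 1))


def se_excite(s: np.ndarray, unit: SEUnit, y: np.ndarray) -> np.ndarray:
    """Gate the channels of ``y`` by the excitation of descriptor ``s``."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (unit.channels,) or y.shape[2] != unit.channels:
        raise ValueError(
            f"length mismatch: descriptor {s.shape}, map channels {y.shape[2]}, unit width {unit.channels}")
    g = unit.gate(Tensor(s[None])).data[0]
    return np.asarray(y) * g[None, None, :]


def mcrt_forward(x: np.ndarray, block: MCRTBlock) -> np.ndarray:
    """Full MCRT block on a single H x W x C map (eval-mode batch norm)."""
    block.eval()
    return _to_hwc(block(_to_nchw(x)))


def mcrt_gradient_check(block: MCRTBlock, x: np.ndarray, eps: float = 1e-4,
                        seed: int = 0) -> float:
    """Compare the analytic input gradient against central finite differences.

    Forms the scalar s(x) = <f(x), u> for a fixed random probe u, computes
    the analytic directional derivative <ds/dx, v> by backpropagation, and
    the same quantity by central differences along v.  Returns the absolute
    deviation.  The analytic gradient necessarily carries the additive
    identity term of the residual connection.
    """
    block.eval().to_dtype(np.float64)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64)
    u = rng.normal(size=x.shape)
    v = rng.normal(size=x.shape)

    def scalar(arr: np.ndarray, need_grad: bool):
        t = Tensor(arr.transpose(2, 0, 1)[None].copy(), requires_grad=need_grad)
        s = (block(t) * Tensor(u.transpose(2, 0, 1)[None])).sum()
        return t, s

    t, s = scalar(x, True)
    s.backward()
    analytic = float((t.grad[0].transpose(1, 2, 0) * v).sum())
    _, sp = scalar(x + eps * v, False)
    _, sm = scalar(x - eps * v, False)
    fd = (float(sp.data) - float(sm.data)) / (2 * eps)
    return abs(analytic - fd)
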