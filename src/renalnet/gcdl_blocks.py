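"""Group Convolution Deep Localization (GCDL) head.

The head consumes the three stage outputs X1, X2, X3 (channel widths 16, 32,
64 at spatial sizes in the ratio 4:2:1) and produces a width-64 feature map
aligned with X3.  It has three sub-sections:

* **Strided fusion** — 3x3 convolutions at strides 4, 2, 1 bring the three
  stages to a common spatial grid; the results are concatenated channel-wise
  and merged by a depthwise-separable 3x3 convolution (X_out), followed by a
  single ReLU.
* **Attention gate** — X_out is globally average-pooled; a small bottleneck
  gate projects the pooled descriptor to one factor per X3 channel, and X3 is
  scaled channel-wise by the gated factors (X_AM).
* **ADSC** — an aggregated depthwise-separable convolution block: four
  parallel depthwise-separable 3x3 branches at dilation rates 1, 2, 4, 6 on
  X_out, concatenated and projected back to 64 channels by a 1x1 convolution.

X_AM and the ADSC output are merged by element-wise addition, which keeps the
head's output at 64 channels in every ablation variant so the same classifier
head can sit on top of all of them.

The internal widths (fusion widths F1, F2, F3, merge width C_f, ADSC branch
width, gate bottleneck) are not free: they are solved by
``model_assembly.solve_reference_config`` against the exact trainable-
parameter budget of the head.  The reference solution is F = (6, 9, 16),
C_f = 45, branch width 21, bottleneck 40.
"""

from __future__ import annotations

import numpy as np

from .nn import (BatchNorm, Conv2d, Dense, DepthwiseConv2d, GlobalAvgPool,
                 Module, Tensor, concat)

ADSC_DILATIONS = (1, 2, 4, 6)


class StridedFusion(Module):
    """Multi-scale strided-convolution fusion producing X_out.

    Per-layer bias/BN policy (fixed by the parameter closure): the three
    strided convolutions carry bias + BN and no activation before
    concatenation; the merge is depthwise (bias) + pointwise (no bias) + BN,
    with a single ReLU after the merge.
    """

    def __init__(self, widths=(6, 9, 16), merge_width: int = 45,
                 in_widths=(16, 32, 64), rng=None):
        super().__init__()
        F1, F2, F3 = widths
        self.widths, self.merge_width, self.in_widths = tuple(widths), merge_width, tuple(in_widths)
        self.k1 = Conv2d(in_widths[0], F1, kernel=3, stride=4, padding=1, rng=rng)
        self.k2 = Conv2d(in_widths[1], F2, kernel=3, stride=2, padding=1, rng=rng)
        self.k3 = Conv2d(in_widths[2], F3, kernel=3, stride=1, padding=1, rng=rng)
        self.bn1, self.bn2, self.bn3 = BatchNorm(F1), BatchNorm(F2), BatchNorm(F3)
        cat = F1 + F2 + F3
        self.k4_dw = DepthwiseConv2d(cat, bias=True, rng=rng)
        self.k4_pw = Conv2d(cat, merge_width, kernel=1, bias=False, rng=rng)
        self.bn4 = BatchNorm(merge_width)

    def forward(self, x1: Tensor, x2: Tensor, x3: Tensor) -> Tensor:
        s1, s2, s3 = x1.shape[2], x2.shape[2], x3.shape[2]
        if not (s1 == 2 * s2 == 4 * s3):
            raise ValueError(
                f"stage spatial sizes must be in ratio 4:2:1, got {s1}, {s2}, {s3}")
        y = concat([self.bn1(self.k1(x1)), self.bn2(self.k2(x2)), self.bn3(self.k3(x3))], axis=1)
        y = self.bn4(self.k4_pw(self.k4_dw(y)))
        return y.relu()


class AttentionGate(Module):
    """Channel-attention gate scaling X3 by factors derived from X_out.

    The pooled C_f descriptor is projected through a biased bottleneck
    (C_f -> hidden, ReLU) and expanded to 64 magnification factors, with batch
    norm on the output. The projection output is deliberately *linear* (no
    squashing): the factors magnify X3 channel-wise, they do not gate it into
    (0,1) the way an SE unit does.
    """

    def __init__(self, in_width: int = 45, hidden: int = 40, out_width: int = 64, rng=None):
        super().__init__()
        self.in_width, self.hidden, self.out_width = in_width, hidden, out_width
        self.fc1 = Dense(in_width, hidden, rng=rng)
        self.fc2 = Dense(hidden, out_width, rng=rng)
        self.bn = BatchNorm(out_width)
        self.pool = GlobalAvgPool()

    def project(self, pooled: Tensor) -> Tensor:
        """(N, C_f) pooled descriptor -> (N, 64) magnification factors."""
        z = self.fc2(self.fc1(pooled).relu())
        return self.bn(z)

    def forward(self, x_out: Tensor, x3: Tensor) -> Tensor:
        g = self.project(self.pool(x_out))
        if g.shape[1] != x3.shape[1]:
            raise ValueError(
                f"gate length {g.shape[1]} does not match stage-3 width {x3.shape[1]}")
        n, c = g.shape
        return x3 * g.reshape(n, c, 1, 1)


class ADSCBlock(Module):
    """Aggregated depthwise-separable convolutions at dilations 1, 2, 4, 6.

    Each branch is depthwise 3x3 (dilation-aware 'same' padding, no bias) +
    pointwise 1x1 (no bias) + BN; branches are concatenated and projected to
    ``out_width`` by a biased 1x1 convolution with BN and ReLU.
    """

    def __init__(self, in_width: int = 45, branch_width: int = 21, out_width: int = 64,
                 dilations=ADSC_DILATIONS, rng=None):
        super().__init__()
        self.in_width, self.branch_width, self.out_width = in_width, branch_width, out_width
        self.dilations = tuple(dilations)
        self.dw = [DepthwiseConv2d(in_width, dilation=d, bias=False, rng=rng) for d in self.dilations]
        self.pw = [Conv2d(in_width, branch_width, kernel=1, bias=False, rng=rng) for _ in self.dilations]
        self.bns = [BatchNorm(branch_width) for _ in self.dilations]
        self.proj = Conv2d(branch_width * len(self.dilations), out_width, kernel=1, rng=rng)
        self.proj_bn = BatchNorm(out_width)

    def forward(self, x_out: Tensor) -> Tensor:
        branches = [bn(pw(dw(x_out))) for dw, pw, bn in zip(self.dw, self.pw, self.bns)]
        y = concat(branches, axis=1)
        return self.proj_bn(self.proj(y)).relu()


class GCDLHead(Module):
    """Full head: strided fusion feeding the attention gate and/or ADSC block.

    ``use_adsc`` / ``use_am`` reproduce the ablation variants; at least one
    branch must be enabled.  When both are on, X_AM and the ADSC output are
    summed element-wise.
    """

    def __init__(self, fusion: StridedFusion | None = None, gate: AttentionGate | None = None,
                 adsc: ADSCBlock | None = None, use_adsc: bool = True, use_am: bool = True,
                 rng=None):
        super().__init__()
        if not (use_adsc or use_am):
            raise ValueError("GCDL head needs at least one of ADSC / attention enabled "
                             "(nearest legal variants: GCNN-3 with ADSC, GCNN-4 with AM)")
        self.use_adsc, self.use_am = use_adsc, use_am
        self.fusion = fusion or StridedFusion(rng=rng)
        self.gate = (gate or AttentionGate(in_width=self.fusion.merge_width, rng=rng)) if use_am else None
        self.adsc = (adsc or ADSCBlock(in_width=self.fusion.merge_width, rng=rng)) if use_adsc else None

    def forward(self, x1: Tensor, x2: Tensor, x3: Tensor) -> Tensor:
        x_out = self.fusion(x1, x2, x3)
        parts = []
        if self.use_am:
            parts.append(self.gate(x_out, x3))
        if self.use_adsc:
            parts.append(self.adsc(x_out))
        y = parts[0]
        for p in parts[1:]:
            y = y + p
        return y


# ---------------------------------------------------------------------------
# Functional surface on single feature maps (H, W, C numpy arrays)
# ---------------------------------------------------------------------------

def _to_nchw(x):
    x = np.asarray(x)
    return Tensor(x.transpose(2, 0, 1)[None].astype(np.float64))


def _to_hwc(t):
    return t.data[0].transpose(1, 2, 0)


def strided_fusion(x1, x2, x3, cfg: StridedFusion) -> np.ndarray:
    """X_out from three H x W x C stage maps (eval-mode BN)."""
    cfg.eval()
    return _to_hwc(cfg(_to_nchw(x1), _to_nchw(x2), _to_nchw(x3)))


def global_pool(x) -> np.ndarray:
    """Per-channel spatial mean of an H x W x C map."""
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected an H x W x C feature map, got shape {x.shape}")
    return x.mean(axis=(0, 1))


def attention_scale(gate_vec, x3, gate: AttentionGate) -> np.ndarray:
    """Project ``gate_vec`` (length C_f) and scale the channels of ``x3``."""
    gate.eval()
    gate_vec = np.asarray(gate_vec, dtype=np.float64)
    if gate_vec.shape != (gate.in_width,):
        raise ValueError(f"gate vector length {gate_vec.shape} != expected {gate.in_width}")
    g = gate.project(Tensor(gate_vec[None])).data[0]
    if g.shape[0] != x3.shape[2]:
        raise ValueError(f"projected gate length {g.shape[0]} != stage-3 width {x3.shape[2]}")
    return np.asarray(x3) * g[None, None, :]


def adsc_forward(x_out, cfg: ADSCBlock) -> np.ndarray:
    cfg.eval()
    return _to_hwc(cfg(_to_nchw(x_out)))


def gcdl_forward(x1, x2, x3, head: GCDLHead) -> np.ndarray:
    """Pre-classifier feature vector: head output, globally average-pooled."""
    head.eval()
    y = head(_to_nchw(x1), _to_nchw(x2), _to_nchw(x3))
    return y.mean((2, 3)).data[0]
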