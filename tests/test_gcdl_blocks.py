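"""GCDL head: strided fusion geometry, global pooling, attention scaling,
dilated depthwise branches, and the assembled head contract."""

import numpy as np
import pytest

from renalnet.gcdl_blocks import (ADSCBlock, AttentionGate, GCDLHead, StridedFusion,
                                  adsc_forward, attention_scale, gcdl_forward,
                                  global_pool, strided_fusion)
from renalnet.nn import Tensor


def _stage_maps(rng, s, widths=(16, 32, 64)):
    return (rng.normal(size=(s, s, widths[0])),
            rng.normal(size=(s // 2, s // 2, widths[1])),
            rng.normal(size=(s // 4, s // 4, widths[2])))


@pytest.mark.parametrize("s", [8, 16, 56, 224])
def test_strided_outputs_share_spatial_size(rng, s):
    fu = StridedFusion(rng=rng)
    x1, x2, x3 = _stage_maps(rng, s)
    out = strided_fusion(x1, x2, x3, fu)
    assert out.shape == (s // 4, s // 4, fu.merge_width)


def test_spatial_ratio_violation_reports_sizes(rng):
    fu = StridedFusion(rng=rng)
    with pytest.raises(ValueError, match="8, 8, 2"):
        strided_fusion(rng.normal(size=(8, 8, 16)), rng.normal(size=(8, 8, 32)),
                       rng.normal(size=(2, 2, 64)), fu)


def test_zero_weight_fusion_gives_zero_map(rng):
    fu = StridedFusion(rng=rng)
    for p in fu.parameters():
        p.data[...] = 0.0
    x1, x2, x3 = _stage_maps(rng, 8)
    assert np.all(strided_fusion(x1, x2, x3, fu) == 0.0)


def test_global_pool_semantics(rng):
    assert np.allclose(global_pool(np.full((4, 6, 3), 2.5)), 2.5)
    m = np.stack([np.ones((2, 2)), np.array([[0.0, 2.0], [4.0, 6.0]])], axis=-1)
    assert np.allclose(global_pool(m), [1.0, 3.0])
    one = rng.normal(size=(1, 1, 5))
    assert np.allclose(global_pool(one), one[0, 0])


def test_attention_scale_matches_loop_oracle(rng):
    gate = AttentionGate(in_width=6, hidden=5, out_width=4, rng=rng)
    gate.eval()
    vec = rng.normal(size=6)
    x3 = rng.normal(size=(3, 3, 4))
    out = attention_scale(vec, x3, gate)
    # independent straight-line projection (eval-mode BN is affine)
    h = np.maximum(vec @ gate.fc1.weight.data + gate.fc1.bias.data, 0.0)
    z = h @ gate.fc2.weight.data + gate.fc2.bias.data
    g = (z - gate.bn.running_mean) / np.sqrt(gate.bn.running_var + gate.bn.eps)
    g = g * gate.bn.gamma.data + gate.bn.beta.data
    expect = np.empty_like(x3)
    for a in range(3):
        for b in range(3):
            for c in range(4):
                expect[a, b, c] = g[c] * x3[a, b, c]
    assert np.allclose(out, expect, atol=1e-6)


def test_attention_multiplicative_identity_and_selectivity(rng):
    gate = AttentionGate(in_width=6, hidden=5, out_width=4, rng=rng)
    for p in gate.parameters():
        p.data[...] = 0.0
    # crafted projection == exactly one: zero weights, unit bias, BN undone
    gate.fc2.bias.data[...] = 1.0
    gate.bn.gamma.data[...] = np.sqrt(1.0 + gate.bn.eps)
    x3 = rng.normal(size=(4, 4, 4))
    assert np.allclose(attention_scale(rng.normal(size=6), x3, gate), x3, atol=1e-7)
    # single nonzero projected entry -> exactly one nonzero output channel
    gate.fc2.bias.data[...] = 0.0
    gate.fc2.bias.data[2] = 1.0
    out = attention_scale(rng.normal(size=6), x3, gate)
    assert np.all(out[..., [0, 1, 3]] == 0.0) and np.any(out[..., 2] != 0.0)


def test_attention_length_mismatch_raises(rng):
    gate = AttentionGate(in_width=6, hidden=5, out_width=4, rng=rng)
    with pytest.raises(ValueError, match="length"):
        attention_scale(rng.normal(size=3), rng.normal(size=(3, 3, 4)), gate)
    with pytest.raises(ValueError, match="stage-3"):
        attention_scale(rng.normal(size=6), rng.normal(size=(3, 3, 7)), gate)


def test_adsc_zero_weights_and_dilation_rates(rng):
    ad = ADSCBlock(in_width=5, branch_width=3, out_width=4, rng=rng)
    assert ad.dilations == (1, 2, 4, 6)
    for p in ad.parameters():
        p.data[...] = 0.0
    assert np.all(adsc_forward(rng.normal(size=(13, 13, 5)), ad) == 0.0)


@pytest.mark.parametrize("d", [1, 2, 4, 6])
def test_dilated_depthwise_impulse_support_is_dilated_stencil(d, rng):
    ad = ADSCBlock(in_width=1, branch_width=1, out_width=1, rng=rng)
    dw = ad.dw[ad.dilations.index(d)]
    dw.weight.data[...] = 1.0
    size = 2 * 6 + 3
    impulse = np.zeros((1, 1, size, size), dtype=np.float64)
    c = size // 2
    impulse[0, 0, c, c] = 1.0
    resp = dw(Tensor(impulse)).data[0, 0]
    nz = set(zip(*np.nonzero(resp)))
    stencil = {(c + i * d, c + j * d) for i in (-1, 0, 1) for j in (-1, 0, 1)}
    assert nz == stencil
    assert resp.shape == (size, size)  # dilation-aware 'same' padding


def test_adsc_preserves_spatial_size(rng):
    ad = ADSCBlock(in_width=5, branch_width=3, out_width=4, rng=rng)
    ad.eval()
    assert adsc_forward(rng.normal(size=(14, 14, 5)), ad).shape == (14, 14, 4)


def test_gcdl_forward_contracts(rng):
    head = GCDLHead(rng=rng)
    head.eval()
    x1, x2, x3 = _stage_maps(rng, 16)
    vec = gcdl_forward(x1, x2, x3, head)
    assert vec.shape == (64,)
    # zero-weight head -> zero feature vector (gate projection is linear)
    for p in head.parameters():
        p.data[...] = 0.0
    assert np.all(gcdl_forward(x1, x2, x3, head) == 0.0)


def test_head_reduced_variants_and_illegal_combo(rng):
    x1, x2, x3 = _stage_maps(rng, 16)
    for kwargs in ({"use_adsc": False}, {"use_am": False}):
        head = GCDLHead(rng=rng, **kwargs)
        head.eval()
        assert gcdl_forward(x1, x2, x3, head).shape == (64,)
    with pytest.raises(ValueError, match="GCNN"):
        GCDLHead(use_adsc=False, use_am=False, rng=rng)
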