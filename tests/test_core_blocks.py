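"""MCRT block: convolution semantics, SE gating, residual identity, gradients,
and the exact trainable-parameter algebra."""

import numpy as np
import pytest

from renalnet.core_blocks import (ConvPath, MCRTBlock, SEUnit, conv_path_forward,
                                  conv_path_param_count, mcrt_forward,
                                  mcrt_gradient_check, mcrt_param_count,
                                  se_excite, se_param_count, se_squeeze)
from renalnet.model_assembly import count_params
from renalnet.nn import Tensor, conv2d


def brute_force_conv(x_hwc, w_oihw, bias, pad=1):
    """Triple-loop cross-correlation with zero padding (independent oracle)."""
    H, W, C = x_hwc.shape
    O, _, kh, kw = w_oihw.shape
    xp = np.zeros((H + 2 * pad, W + 2 * pad, C))
    xp[pad:pad + H, pad:pad + W] = x_hwc
    out = np.zeros((H, W, O))
    for o in range(O):
        for a in range(H):
            for b in range(W):
                acc = 0.0
                for j in range(C):
                    for u in range(kh):
                        for v in range(kw):
                            acc += w_oihw[o, j, u, v] * xp[a + u, b + v, j]
                out[a, b, o] = acc + bias[o]
    return out


@pytest.mark.parametrize("shape,channels_out", [((5, 5, 3), 3), ((4, 3, 2), 2)])
def test_conv_matches_bruteforce_correlation(rng, shape, channels_out):
    x = rng.normal(size=shape)
    w = rng.normal(size=(channels_out, shape[2], 3, 3))
    b = rng.normal(size=channels_out)
    got = conv2d(Tensor(x.transpose(2, 0, 1)[None]), Tensor(w), Tensor(b), padding=1)
    expect = brute_force_conv(x, w, b)
    assert np.allclose(got.data[0].transpose(1, 2, 0), expect, atol=1e-6)


def test_interior_pixel_is_cross_channel_window_sum(rng):
    # 3x3x2 input, all-ones 3x3 kernels: the interior output pixel is the sum
    # of the full 3x3 neighbourhood across both channels.
    x = rng.normal(size=(3, 3, 2))
    w = np.ones((1, 2, 3, 3))
    out = conv2d(Tensor(x.transpose(2, 0, 1)[None]), Tensor(w), None, padding=1)
    assert np.isclose(out.data[0, 0, 1, 1], x.sum(), atol=1e-6)


def test_conv_path_preserves_shape_and_zero_maps(rng):
    path = ConvPath(16, rng=rng)
    x = rng.normal(size=(8, 8, 16))
    assert conv_path_forward(x, path).shape == (8, 8, 16)
    for p in path.parameters():
        p.data[...] = 0.0
    assert np.all(conv_path_forward(x, path) == 0.0)


def test_conv_path_channel_mismatch_raises(rng):
    path = ConvPath(16, rng=rng)
    with pytest.raises(ValueError, match="16"):
        conv_path_forward(rng.normal(size=(8, 8, 4)), path)


def test_se_squeeze_is_spatial_mean():
    const = np.full((6, 7, 5), 3.25)
    assert np.allclose(se_squeeze(const), 3.25)
    hand = np.array([[1.0, 2.0], [3.0, 5.0]]).reshape(2, 2, 1)
    assert np.isclose(se_squeeze(hand)[0], 2.75)
    assert se_squeeze(np.zeros((7, 9, 64))).shape == (64,)


def test_se_excite_zero_weights_halves_input(rng):
    unit = SEUnit(4, 2, rng=rng)
    for p in unit.parameters():
        p.data[...] = 0.0
    y = rng.normal(size=(3, 3, 4))
    out = se_excite(se_squeeze(y), unit, y)
    assert np.allclose(out, 0.5 * y, atol=1e-7)


def test_se_weight_shapes_c64_r2(rng):
    unit = SEUnit(64, 2, rng=rng)
    # stored as (in, out) dense matrices: W1 maps C -> C/r, W2 maps back
    assert unit.fc1.weight.shape == (64, 32)
    assert unit.fc2.weight.shape == (32, 64)


def test_se_excite_matches_straight_line_evaluation(rng):
    unit = SEUnit(4, 2, rng=rng)
    y = rng.normal(size=(5, 5, 4))
    s = se_squeeze(y)
    # independent straight-line evaluation of the excitation
    h = np.maximum(s @ unit.fc1.weight.data + unit.fc1.bias.data, 0.0)
    g = 1.0 / (1.0 + np.exp(-(h @ unit.fc2.weight.data + unit.fc2.bias.data)))
    assert np.allclose(se_excite(s, unit, y), y * g[None, None, :], atol=1e-6)


def test_se_gate_bounded_and_gate_depends_only_on_descriptor(rng):
    unit = SEUnit(8, 4, rng=rng)
    y = rng.normal(size=(4, 4, 8))
    s = se_squeeze(y)
    g = se_excite(s, unit, np.ones_like(y))  # gate values themselves
    assert np.all(g > 0.0) and np.all(g < 1.0)
    lam = 3.7
    y2 = y.copy()
    y2[..., 3] *= lam
    out, out2 = se_excite(s, unit, y), se_excite(s, unit, y2)
    assert np.allclose(out2[..., 3], lam * out[..., 3])


def test_se_non_integral_ratio_raises():
    with pytest.raises(ValueError, match="C/r"):
        SEUnit(10, 4)


def test_mcrt_zero_weights_is_exact_identity(rng):
    block = MCRTBlock(8, (2, 4, 8), rng=rng).zero_()
    x = rng.normal(size=(6, 6, 8))
    assert np.array_equal(mcrt_forward(x, block), x)


def test_mcrt_output_shape_and_ratio_sets(rng):
    for ratios in [(2, 4, 8), (2, 2, 2), (8, 8, 8)]:
        block = MCRTBlock(16, ratios, rng=rng)
        x = rng.normal(size=(8, 8, 16))
        assert mcrt_forward(x, block).shape == x.shape


@pytest.mark.parametrize("C,expected", [(16, 7662), (32, 30044), (64, 118968)])
def test_mcrt_parameter_count_closed_form_vs_layer_walk(C, expected):
    block = MCRTBlock(C, (2, 4, 8), rng=np.random.default_rng(0))
    assert mcrt_param_count(C, (2, 4, 8)) == expected
    assert count_params(block).total == expected


@pytest.mark.parametrize("C", [16, 32, 64])
@pytest.mark.parametrize("r", [2, 4, 8])
def test_parameter_algebra_holds_on_grid(C, r):
    unit = SEUnit(C, r, rng=np.random.default_rng(0))
    assert count_params(unit).total == se_param_count(C, r) == 2 * C * C // r + C // r + C
    path = ConvPath(C, rng=np.random.default_rng(0))
    assert count_params(path).total == conv_path_param_count(C) == 9 * C * C + 5 * C


def test_uniform_ratio_totals_reproduce_printed_deltas():
    widths = (16, 32, 64)
    tot = {r: sum(mcrt_param_count(C, (r, r, r)) for C in widths) for r in (2, 4, 8)}
    assert tot[2] - tot[4] == 8148
    assert tot[4] - tot[8] == 4074


def test_gradient_check_seeded_block(rng):
    block = MCRTBlock(4, (2, 2, 4), rng=rng)
    x = np.random.default_rng(7).normal(size=(4, 4, 4))
    assert mcrt_gradient_check(block, x, eps=1e-4, seed=3) < 1e-3


def test_zero_block_input_gradient_is_identity(rng):
    block = MCRTBlock(4, (2, 4, 4), rng=rng).zero_().eval().to_dtype(np.float64)
    x = Tensor(np.random.default_rng(5).normal(size=(1, 4, 4, 4)), requires_grad=True)
    block(x).sum().backward()
    assert np.allclose(x.grad, 1.0)


def test_forward_invariant_to_path_order(rng):
    block = MCRTBlock(4, (2, 2, 2), rng=rng).eval()
    x = np.random.default_rng(9).normal(size=(5, 5, 4))
    before = mcrt_forward(x, block)
    block.paths = block.paths[::-1]
    block.se_units = block.se_units[::-1]
    assert np.allclose(mcrt_forward(x, block), before, atol=1e-12)
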