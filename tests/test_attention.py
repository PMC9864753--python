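"""Spatial and channel feature units against straight-line loop oracles.

The oracles re-implement the pooling, convolution, batch-norm, MLP and
sigmoid arithmetic with explicit Python loops, independently of the
autodiff engine.
"""

import numpy as np
import pytest

from lvseg.attention import (ChannelFeatureUnit, SpatialFeatureUnit,
                             channel_attention, channel_pool, refine_channel,
                             refine_spatial, spatial_attention, spatial_pool)
from lvseg.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ------------------------------------------------------------------ pooling

def test_spatial_pool_hand_example():
    x = np.array([[[1.0, 2.0, 3.0]]])  # one pixel, three channels
    avg, mx = spatial_pool(x)
    assert avg[0, 0] == 2.0 and mx[0, 0] == 3.0


def test_channel_pool_hand_example():
    x = np.array([[1.0], [2.0], [3.0], [4.0]]).reshape(2, 2, 1)
    avg, mx = channel_pool(x)
    assert avg[0] == 2.5 and mx[0] == 4.0


def test_pools_of_constant_input():
    x = np.full((5, 4, 7), 3.25)
    avg, mx = spatial_pool(x)
    np.testing.assert_array_equal(avg, 3.25)
    np.testing.assert_array_equal(mx, 3.25)
    avg_c, max_c = channel_pool(x)
    np.testing.assert_array_equal(avg_c, 3.25)
    np.testing.assert_array_equal(max_c, 3.25)


def test_pools_match_loop_oracle(rng):
    x = rng.normal(size=(8, 8, 16))
    avg, mx = spatial_pool(x)
    avg_c, max_c = channel_pool(x)
    for i in range(8):
        for j in range(8):
            assert abs(avg[i, j] - sum(x[i, j]) / 16) < 1e-6
            assert abs(mx[i, j] - max(x[i, j])) < 1e-6
    for c in range(16):
        vals = [x[i, j, c] for i in range(8) for j in range(8)]
        assert abs(avg_c[c] - sum(vals) / 64) < 1e-6
        assert abs(max_c[c] - max(vals)) < 1e-6


def test_spatial_pool_invariant_under_channel_permutation(rng):
    x = rng.normal(size=(6, 5, 9))
    perm = rng.permutation(9)
    a1, m1 = spatial_pool(x)
    a2, m2 = spatial_pool(x[:, :, perm])
    np.testing.assert_allclose(a1, a2, atol=1e-12)
    np.testing.assert_allclose(m1, m2, atol=1e-12)


def test_channel_pool_equivariant_under_channel_permutation(rng):
    x = rng.normal(size=(6, 5, 9))
    perm = rng.permutation(9)
    a1, m1 = channel_pool(x)
    a2, m2 = channel_pool(x[:, :, perm])
    np.testing.assert_allclose(a1[perm], a2, atol=1e-12)
    np.testing.assert_allclose(m1[perm], m2, atol=1e-12)


# ---------------------------------------------------------------- attention

def test_spatial_attention_zero_weights_is_half(rng):
    avg, mx = spatial_pool(rng.normal(size=(6, 6, 4)))
    att = spatial_attention(avg, mx, np.zeros((1, 2, 7, 7)), bias=0.0)
    np.testing.assert_allclose(att, 0.5, atol=1e-12)


def test_spatial_attention_strictly_inside_unit_interval(rng):
    avg, mx = spatial_pool(rng.normal(size=(6, 6, 4)))
    att = spatial_attention(avg, mx, rng.normal(size=(1, 2, 3, 3)))
    assert (att > 0).all() and (att < 1).all()


def test_spatial_attention_matches_loop_oracle(rng):
    avg, mx = spatial_pool(rng.normal(size=(5, 5, 3)))
    w = rng.normal(size=(1, 2, 3, 3))
    b = 0.3
    att = spatial_attention(avg, mx, w, bias=b)
    stacked = np.stack([avg, mx])
    padded = np.pad(stacked, ((0, 0), (1, 1), (1, 1)))
    for i in range(5):
        for j in range(5):
            z = b
            for c in range(2):
                for di in range(3):
                    for dj in range(3):
                        z += padded[c, i + di, j + dj] * w[0, c, di, dj]
            assert abs(att[i, j] - _sigmoid(z)) < 1e-5


def test_channel_attention_zero_mlp_is_half(rng):
    c = 8
    avg, mx = channel_pool(rng.normal(size=(4, 4, c)))
    weights = (np.zeros((c, 2)), np.zeros(2), np.zeros((2, c)), np.zeros(c))
    np.testing.assert_allclose(channel_attention(avg, mx, weights), 0.5, atol=1e-12)


def test_channel_attention_matches_matrix_oracle(rng):
    c, h = 8, 4
    avg, mx = channel_pool(rng.normal(size=(4, 4, c)))
    w1, b1 = rng.normal(size=(c, h)), rng.normal(size=h)
    w2, b2 = rng.normal(size=(h, c)), rng.normal(size=c)
    att = channel_attention(avg, mx, (w1, b1, w2, b2))
    for k in range(c):
        z = 0.0
        for vec in (avg, mx):
            hidden = [max(0.0, sum(vec[i] * w1[i, j] for i in range(c)) + b1[j])
                      for j in range(h)]
            z += sum(hidden[j] * w2[j, k] for j in range(h)) + b2[k]
        assert abs(att[k] - _sigmoid(z)) < 1e-5


def test_channel_attention_permutation_equivariance(rng):
    c, h = 6, 3
    x = rng.normal(size=(5, 5, c))
    perm = rng.permutation(c)
    w1, b1 = rng.normal(size=(c, h)), rng.normal(size=h)
    w2, b2 = rng.normal(size=(h, c)), rng.normal(size=c)
    att = channel_attention(*channel_pool(x), (w1, b1, w2, b2))
    # permuting channels and permuting the MLP's rows/columns accordingly
    att_p = channel_attention(*channel_pool(x[:, :, perm]),
                              (w1[perm], b1, w2[:, perm], b2[perm]))
    np.testing.assert_allclose(att[perm], att_p, atol=1e-10)


# --------------------------------------------------------------- refinement

def test_refine_spatial_broadcast_and_identity(rng):
    x = rng.normal(size=(4, 4, 6))
    np.testing.assert_allclose(refine_spatial(x, np.full((4, 4), 0.5)), x / 2)
    eps = 1e-9
    np.testing.assert_allclose(refine_spatial(x, np.full((4, 4), 1 - eps)), x,
                               atol=1e-7)
    att = rng.uniform(size=(4, 4))
    out = refine_spatial(x, att)
    for i in range(4):
        for j in range(4):
            for c in range(6):
                assert abs(out[i, j, c] - x[i, j, c] * att[i, j]) < 1e-6


def test_refine_channel_broadcast(rng):
    x = rng.normal(size=(3, 3, 4))
    np.testing.assert_allclose(refine_channel(x, np.ones(4)), x)
    x2 = x.copy()
    x2[:, :, 0] = 1.0
    att = np.array([0.5, 1.0, 1.0, 1.0])
    np.testing.assert_allclose(refine_channel(x2, att)[:, :, 0], 0.5)
    att_r = rng.uniform(size=4)
    out = refine_channel(x, att_r)
    for i in range(3):
        for j in range(3):
            for c in range(4):
                assert abs(out[i, j, c] - x[i, j, c] * att_r[c]) < 1e-6


def test_refinement_shape_errors():
    with pytest.raises(ValueError):
        refine_spatial(np.zeros((4, 4, 2)), np.zeros((3, 4)))
    with pytest.raises(ValueError):
        refine_channel(np.zeros((4, 4, 2)), np.zeros(3))
    with pytest.raises(ValueError):
        ChannelFeatureUnit(channels=6, reduction=4)


# ----------------------------------------------- end-to-end unit vs oracle

def _sfu_oracle(x_hwc, unit):
    """Eqs of the spatial unit, straight-line: pool, concat, conv, BN
    (inference statistics), sigmoid, multiply."""
    h, w, c = x_hwc.shape
    avg = x_hwc.mean(axis=2)
    mx = x_hwc.max(axis=2)
    kw = unit.conv.weight.data
    k = kw.shape[-1]
    pad = k // 2
    stacked = np.pad(np.stack([avg, mx]), ((0, 0), (pad, pad), (pad, pad)))
    out = np.empty((h, w, c))
    gamma = unit.bn.weight.data.ravel()[0]
    beta = unit.bn.bias.data.ravel()[0]
    rm = unit.bn.buf_running_mean.ravel()[0]
    rv = unit.bn.buf_running_var.ravel()[0]
    for i in range(h):
        for j in range(w):
            z = unit.conv.bias.data[0]
            for ch in range(2):
                for di in range(k):
                    for dj in range(k):
                        z += stacked[ch, i + di, j + dj] * kw[0, ch, di, dj]
            z = gamma * (z - rm) / np.sqrt(rv + unit.bn.eps) + beta
            a = _sigmoid(z)
            for cc in range(c):
                out[i, j, cc] = x_hwc[i, j, cc] * a
    return out


def _cfu_oracle(x_hwc, unit):
    h, w, c = x_hwc.shape
    avg = x_hwc.mean(axis=(0, 1))
    mx = x_hwc.max(axis=(0, 1))
    w1, b1 = unit.fc1.weight.data, unit.fc1.bias.data
    w2, b2 = unit.fc2.weight.data, unit.fc2.bias.data
    z = np.zeros(c)
    for vec in (avg, mx):
        hidden = np.maximum(vec @ w1 + b1, 0.0)
        z += hidden @ w2 + b2
    att = _sigmoid(z)
    return x_hwc * att


@pytest.mark.parametrize("shape", [(4, 4, 8), (8, 8, 16)])
def test_sfu_end_to_end_matches_oracle(shape, rng):
    x = rng.normal(size=shape)
    unit = SpatialFeatureUnit(kernel_size=7, rng=np.random.default_rng(11))
    unit.bn.buf_running_mean[...] = 0.2
    unit.bn.buf_running_var[...] = 1.7
    unit.eval()
    t = Tensor(np.moveaxis(x, -1, 0)[None])
    got = np.moveaxis(unit(t).data[0], 0, -1)
    np.testing.assert_allclose(got, _sfu_oracle(x, unit), atol=1e-5)
    att = unit.attention(t).data
    assert (att > 0).all() and (att < 1).all()


@pytest.mark.parametrize("shape", [(4, 4, 8), (8, 8, 16)])
def test_cfu_end_to_end_matches_oracle(shape, rng):
    x = rng.normal(size=shape)
    unit = ChannelFeatureUnit(shape[-1], reduction=4, rng=np.random.default_rng(12))
    unit.eval()
    t = Tensor(np.moveaxis(x, -1, 0)[None])
    got = np.moveaxis(unit(t).data[0], 0, -1)
    np.testing.assert_allclose(got, _cfu_oracle(x, unit), atol=1e-5)
    att = unit.attention(t).data
    assert (att > 0).all() and (att < 1).all()


def test_refinement_with_zero_attention_annihilates(rng):
    x = Tensor(rng.normal(size=(1, 4, 5, 5)))
    np.testing.assert_array_equal((x * 0.0).data, 0.0)
    np.testing.assert_array_equal((x * 1.0).data, x.data)
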