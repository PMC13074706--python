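"""Dual-spectral fusion: IR backbone, CBAM gates, multi-scale, ternary fuse."""

import numpy as np
import pytest

from seedfusion.dsf import (CBAM, FusionMLP, IRBackbone, MultiScaleAggregate,
                            VisStem)
from seedfusion.nn import AdamW, Tensor


# ------------------------------------------------------------- IR backbone
def test_ir_backbone_shape_stride_and_determinism():
    bb = IRBackbone(channels=8, seed=0)
    x = np.random.default_rng(0).normal(size=(2, 64, 64))
    a = bb(x)
    assert a.shape == (2, 8, 16, 16)  # two stride-2 stages -> 1/4
    np.testing.assert_array_equal(a.data, bb(x).data)


def test_ir_backbone_zero_input_bias_free_gives_zero_map():
    bb = IRBackbone(channels=4, seed=0)
    bb.conv1.bias.data[:] = 0
    bb.conv2.bias.data[:] = 0
    out = bb(np.zeros((1, 32, 32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_ir_backbone_rejects_wrong_channel_count():
    bb = IRBackbone(channels=4, seed=0)
    with pytest.raises(ValueError):
        bb(Tensor(np.zeros((1, 3, 32, 32))))


# -------------------------------------------------------------------- CBAM
def test_cbam_constant_input_mc_uses_doubled_mlp():
    cbam = CBAM(channels=6, seed=1)
    x = np.ones((1, 6, 5, 5)) * np.arange(1, 7).reshape(1, 6, 1, 1)
    _, mc, _ = cbam(Tensor(x))
    pooled = Tensor(x.mean(axis=(2, 3)))
    expected = (cbam.mlp(pooled) * 2.0).sigmoid()
    np.testing.assert_allclose(mc.data, expected.data, atol=1e-12)


def test_cbam_zero_input_zero_bias_gives_half_gates_and_zero_output():
    cbam = CBAM(channels=4, seed=0)
    for lin in (cbam.mlp.modules[0], cbam.mlp.modules[2]):
        lin.bias.data[:] = 0
    cbam.spatial_conv.bias.data[:] = 0
    out, mc, ms = cbam(Tensor(np.zeros((1, 4, 6, 6))))
    np.testing.assert_allclose(mc.data, 0.5, atol=1e-12)
    np.testing.assert_allclose(ms.data, 0.5, atol=1e-12)
    np.testing.assert_array_equal(out.data, 0.0)


def test_cbam_gates_bounded_and_never_amplify():
    rng = np.random.default_rng(2)
    cbam = CBAM(channels=8, seed=2)
    x = rng.normal(size=(3, 8, 10, 10))
    out, mc, ms = cbam(Tensor(x))
    assert np.all(mc.data > 0) and np.all(mc.data < 1)
    assert np.all(ms.data > 0) and np.all(ms.data < 1)
    assert np.all(np.abs(out.data) <= np.abs(x))
    assert out.shape == x.shape


# -------------------------------------------------------------- multiscale
def test_multiscale_preserves_spatial_dims_and_nonnegative():
    ms = MultiScaleAggregate(channels=6, seed=0)
    x = Tensor(np.random.default_rng(3).normal(size=(2, 6, 9, 9)))
    out = ms(x)
    assert out.shape[2:] == (9, 9)
    assert np.all(out.data >= 0)


def test_multiscale_identity_kernels_reduce_to_relu():
    """Delta branch kernels + averaging reduction pass the input through."""
    c = 3
    ms = MultiScaleAggregate(channels=c, branch_channels=c, seed=0,
                             preconv=False)
    for conv, k in zip(ms.branches, MultiScaleAggregate.KERNELS):
        conv.weight.data[:] = 0
        for ch in range(c):
            conv.weight.data[ch, ch, k // 2, k // 2] = 1.0
        conv.bias.data[:] = 0
    ms.reduce.weight.data[:] = 0
    for ch in range(c):
        for branch in range(len(MultiScaleAggregate.KERNELS)):
            ms.reduce.weight.data[ch, branch * c + ch, 0, 0] = 0.25
    ms.reduce.bias.data[:] = 0
    x = np.random.default_rng(4).normal(size=(1, c, 7, 7))
    out = ms(Tensor(x))
    np.testing.assert_allclose(out.data, np.maximum(x, 0.0), atol=1e-12)


# ------------------------------------------------------------------ fusion
def test_fusion_zero_mlp_gives_zero_output():
    fuse = FusionMLP(4, 4, 8, d_fuse=6, seed=0)
    for p in fuse.parameters():
        p.data = np.zeros_like(p.data)
    rng = np.random.default_rng(5)
    out = fuse(Tensor(rng.normal(size=(2, 4, 3, 3))),
               Tensor(rng.normal(size=(2, 4, 3, 3))),
               Tensor(rng.normal(size=(2, 8))))
    np.testing.assert_array_equal(out.fs.data, 0.0)


def test_fusion_concat_width_bookkeeping():
    fuse = FusionMLP(4, 6, 8, seed=0)
    assert fuse.in_dim == 18
    with pytest.raises(ValueError):
        fuse(None, None, Tensor(np.zeros((1, 5))))


def test_fusion_single_layer_matches_hand_affine():
    from seedfusion.nn import Linear, Sequential
    fuse = FusionMLP(2, 2, 2, d_fuse=2, seed=0)
    rng = np.random.default_rng(6)
    lin = Linear(6, 2, rng)
    fuse.net = Sequential(lin)
    fuse.in_dim = 6
    fir = rng.normal(size=(1, 2, 2, 2))
    fvis = rng.normal(size=(1, 2, 2, 2))
    fres = rng.normal(size=(1, 2))
    out = fuse(Tensor(fir), Tensor(fvis), Tensor(fres))
    cat = np.concatenate([fir.mean(axis=(2, 3)), fvis.mean(axis=(2, 3)),
                          fres], axis=1)
    np.testing.assert_allclose(out.fs.data,
                               cat @ lin.weight.data + lin.bias.data,
                               atol=1e-12)


def test_fusion_sensitive_to_branch_order():
    fuse = FusionMLP(3, 3, 2, seed=1)
    rng = np.random.default_rng(7)
    a = Tensor(rng.normal(size=(1, 3, 2, 2)))
    b = Tensor(rng.normal(size=(1, 3, 2, 2)))
    fres = Tensor(rng.normal(size=(1, 2)))
    ab = fuse(a, b, fres).fs.data
    ba = fuse(b, a, fres).fs.data
    assert not np.allclose(ab, ba)


def test_gradients_reach_all_trainable_dsf_blocks():
    """With a frozen upstream, CBAM / multiscale / fusion all get gradients."""
    rng = np.random.default_rng(8)
    bb = IRBackbone(channels=4, seed=3)
    stem = VisStem(channels=4, seed=3)
    cbam = CBAM(channels=4, seed=3)
    ms = MultiScaleAggregate(channels=4, seed=3)
    fuse = FusionMLP(4, 4, 2, d_fuse=4, seed=3)
    ir = rng.normal(size=(2, 16, 16))
    rgb = rng.normal(size=(2, 16, 16, 3))
    fres = Tensor(rng.normal(size=(2, 2)))
    fir_att, _, _ = cbam(bb(ir))
    out = fuse(fir_att, ms(stem(rgb)), fres)
    loss = (out.fs ** 2.0).sum()
    loss.backward()
    for module in (cbam, ms, fuse):
        norms = [np.abs(p.grad).sum() for p in module.parameters()
                 if p.grad is not None]
        assert norms and sum(norms) > 0
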