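"""Contracts of the dual-branch feature mixer."""

import math

import numpy as np
import pytest

from bsdnet import autograd as ag
from bsdnet.autograd import Tensor
from bsdnet.dbfm import (DbfmSpec, DualBranchFeatureMixer,
                         GlobalInformationBranch, space_to_depth,
                         space_to_depth_inverse)
from bsdnet.model import ModelConfig, build_model


def rng(seed=0):
    return np.random.default_rng(seed)


def test_global_branch_preserves_shape():
    gb = GlobalInformationBranch(32, rng=rng()).eval()
    out = gb(Tensor(np.zeros((1, 32, 16, 16), np.float32)))
    assert out.shape == (1, 32, 16, 16)


def test_global_branch_residual_identity_with_zeroed_projection():
    gb = GlobalInformationBranch(16, rng=rng()).eval()
    gb.proj.weight.data[:] = 0.0
    gb.proj.bias.data[:] = 0.0
    x = rng(1).normal(0, 1, (2, 16, 8, 8)).astype(np.float32)
    out = gb(Tensor(x))
    assert np.array_equal(out.data, x)


def test_global_branch_scalar_hand_trace():
    """1-channel 1x1 micro-case, all conv weights 1, BN bypassed, input 1:
    trace SiLU -> split -> GELU gate -> product -> residual by hand."""
    gb = GlobalInformationBranch(1, rng=rng()).eval()
    gb.expand.conv.weight.data[:] = 1.0
    gb.expand.bn.identity_()
    gb.dw.weight.data[:] = 1.0
    gb.dw.bias.data[:] = 0.0
    gb.proj.weight.data[:] = 1.0
    gb.proj.bias.data[:] = 0.0
    out = gb(Tensor(np.ones((1, 1, 1, 1), np.float32)))
    s = 1.0 / (1.0 + math.exp(-1.0))          # SiLU(1) = sigmoid(1)
    f1 = f2 = s
    g = f1 + 1.0                               # dw 3x3 at 1x1 spatial = centre tap
    gelu = g * 0.5 * (1.0 + math.erf(g / math.sqrt(2.0)))
    expected = gelu * f2 + 1.0
    assert abs(out.data.item() - expected) < 1e-6


def test_space_to_depth_offset_order():
    """[[a, b], [c, d]] -> channels [a], [c], [b], [d] at 1x1 spatial."""
    grid = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], np.float32))
    out = space_to_depth(grid)
    assert out.shape == (1, 4, 1, 1)
    assert out.data.reshape(-1).tolist() == [1.0, 3.0, 2.0, 4.0]


def test_space_to_depth_is_a_bijection():
    x = rng(2).normal(0, 1, (2, 3, 8, 10)).astype(np.float32)
    y = space_to_depth(Tensor(x))
    assert y.shape == (2, 12, 4, 5)
    assert np.array_equal(space_to_depth_inverse(y.data), x)
    # multiset of values and total element count preserved
    assert y.data.size == x.size
    assert np.array_equal(np.sort(y.data.ravel()), np.sort(x.ravel()))


def test_space_to_depth_rejects_odd_dims():
    with pytest.raises(ValueError):
        space_to_depth(Tensor(np.zeros((1, 1, 3, 4), np.float32)))


def test_mixer_halves_spatial_dims():
    spec = DbfmSpec(in_channels=16, out_channels=32, out_repeats=1)
    mixer = DualBranchFeatureMixer(spec, rng=rng()).eval()
    out = mixer(Tensor(np.zeros((1, 16, 16, 12), np.float32)))
    assert out.shape == (1, 32, 8, 6)
    with pytest.raises(ValueError):
        mixer(Tensor(np.zeros((1, 16, 15, 12), np.float32)))


def test_fuse_requires_matching_spatial_dims_and_orders_inputs():
    spec = DbfmSpec(in_channels=8, out_channels=8)
    mixer = DualBranchFeatureMixer(spec, rng=rng(3)).eval()
    ld = Tensor(rng(4).normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
    gi = Tensor(rng(5).normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
    with pytest.raises(ValueError):
        mixer.fuse_dual_branch(ld, Tensor(np.zeros((1, 8, 2, 2), np.float32)))
    # concat order is (LD, GI): swapping the operands changes the output
    a = mixer.fuse_dual_branch(ld, gi).data
    b = mixer.fuse_dual_branch(gi, ld).data
    assert not np.allclose(a, b)


def test_fuse_with_constructed_identity_weights():
    """1x1 fuse conv set to identity on the LD half and zero elsewhere,
    BN bypassed: the fused map equals SiLU(concat)[:c] = SiLU applied to LD."""
    spec = DbfmSpec(in_channels=8, out_channels=8)
    mixer = DualBranchFeatureMixer(spec, rng=rng(6)).eval()
    w = np.zeros((8, 16, 1, 1), np.float32)
    for i in range(8):
        w[i, i, 0, 0] = 1.0
    mixer.fuse.conv.weight.data = w
    mixer.fuse.bn.identity_()
    ld = rng(7).normal(0, 1, (1, 8, 4, 4)).astype(np.float32)
    gi = rng(8).normal(0, 1, (1, 8, 4, 4)).astype(np.float32)
    out = mixer.fuse_dual_branch(Tensor(ld), Tensor(gi)).data
    expected = ld * (1.0 / (1.0 + np.exp(-ld)))
    assert np.allclose(out, expected, atol=1e-6)


def test_mixer_is_deterministic_in_inference():
    spec = DbfmSpec(in_channels=8, out_channels=16)
    mixer = DualBranchFeatureMixer(spec, rng=rng(9)).eval()
    x = rng(10).normal(0, 1, (1, 8, 8, 8)).astype(np.float32)
    with ag.no_grad():
        a = mixer(Tensor(x)).data
        b = mixer(Tensor(x)).data
    assert np.array_equal(a, b)


@pytest.mark.parametrize("trial", range(5))
def test_gradient_reaches_every_input_element(trial):
    spec = DbfmSpec(in_channels=8, out_channels=8)
    mixer = DualBranchFeatureMixer(spec, rng=rng(20 + trial)).train()
    x = Tensor(rng(30 + trial).normal(0, 1, (1, 8, 8, 8)).astype(np.float32))
    x.requires_grad = True
    out = mixer(x)
    proj = rng(40 + trial).normal(0, 1, out.shape).astype(np.float32)
    (out * proj).sum().backward()
    assert x.grad is not None and (x.grad != 0).all()


def test_global_branch_influence_extends_beyond_local_footprint():
    """While training, a single-pixel perturbation reaches far positions
    (the normalisation statistics and gating couple the whole map)."""
    gb = GlobalInformationBranch(4, rng=rng(50)).train()
    x = rng(51).normal(0, 1, (1, 4, 12, 12)).astype(np.float32)
    base = gb(Tensor(x)).data.copy()
    xp = x.copy()
    xp[0, 0, 6, 6] += 5.0
    pert = gb(Tensor(xp)).data
    diff = np.abs(pert - base).max(axis=(0, 1))
    far = diff.copy()
    far[3:10, 3:10] = 0.0  # mask everything within the 3x3-ish neighbourhood
    assert far.max() > 1e-6


def test_three_mixer_stages_add_the_published_parameter_budget():
    base = build_model(ModelConfig(n_categories=200, scale="medium",
                                   use_dbfm=False))
    full = build_model(ModelConfig(n_categories=200, scale="medium",
                                   use_dbfm=True))
    delta = (full.num_parameters() - base.num_parameters()) / 1e6
    assert round(delta, 1) == 4.7
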