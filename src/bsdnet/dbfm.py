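"""Dual-branch feature mixer (DBFM).

A downsampling stage that mixes a local-detail branch (a C2F block) with a
gated global-information branch, then halves the spatial resolution by
rearranging the fused map into its four strided sub-grids (space-to-depth)
and mixing channels.  The global branch is a gated-MLP-style unit: a 1x1
conv expands C -> 2C, the two halves F1 and F2 are split off, a depthwise
3x3 over (F1 + F) is gated by an exact-erf GELU, multiplied elementwise by
F2, projected back by a 1x1 conv, and added residually to the input:

    F1, F2 = split(SiLU(BN(conv1x1(F))))
    GI     = conv1x1(GELU(dwconv3x3(F1 + F)) * F2) + F

The fused map SiLU(BN(conv1x1(cat(LD, GI)))) is added back to the input
pathway, space-to-depth rearranged, 1x1-mixed to the output width, and
passed through a trailing channel-mixing C2F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import C2F, ConvBNSiLU
from .nn import Conv2d, Module


@dataclass(frozen=True)
class DbfmSpec:
    """Configuration of one mixer stage.

    local_repeats / local_hidden size the input-resolution C2F branch;
    out_repeats / out_hidden size the trailing channel-mixing C2F at the
    output width.  Hidden widths default to half the corresponding width.
    """
    in_channels: int
    out_channels: int
    local_repeats: int = 1
    local_hidden: int | None = None
    out_repeats: int = 1
    out_hidden: int | None = None
    dw_kernel: int = 3

    def __post_init__(self):
        if self.in_channels % 2:
            raise ValueError("in_channels must be even (the global branch splits in two)")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


class GlobalInformationBranch(Module):
    """Gated global-context unit; output has the input's shape (outer residual)."""

    def __init__(self, c: int, dw_kernel: int = 3, rng=None):
        super().__init__()
        if (2 * c) % 2:
            raise ValueError("expanded channel count must be even")
        self.c = c
        self.expand = ConvBNSiLU(c, 2 * c, 1, rng=rng)
        self.dw = Conv2d(c, c, dw_kernel, bias=True, groups=c, rng=rng)
        self.proj = Conv2d(c, c, 1, bias=True, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        y = self.expand(f)
        f1, f2 = y[:, : self.c], y[:, self.c:]
        gate = ag.gelu(self.dw(f1 + f))
        return self.proj(gate * f2) + f

    def profile(self, h, w):
        f = self.expand.profile(h, w)[0] + self.dw.profile(h, w)[0] + self.proj.profile(h, w)[0]
        return f, (h, w)


def space_to_depth(fd: Tensor) -> Tensor:
    """Rearrange (c, h, w) -> (4c, h/2, w/2) by stacking the four strided
    sub-grids at offsets (0,0), (1,0), (0,1), (1,1).  Lossless."""
    if fd.shape[2] % 2 or fd.shape[3] % 2:
        raise ValueError("space_to_depth requires even spatial dims")
    return ag.concat(
        [fd[:, :, 0::2, 0::2], fd[:, :, 1::2, 0::2],
         fd[:, :, 0::2, 1::2], fd[:, :, 1::2, 1::2]],
        axis=1,
    )


def space_to_depth_inverse(y: np.ndarray) -> np.ndarray:
    """Invert the rearrangement on a raw array (used to check bijectivity)."""
    n, c4, h2, w2 = y.shape
    c = c4 // 4
    out = np.empty((n, c, h2 * 2, w2 * 2), dtype=y.dtype)
    out[:, :, 0::2, 0::2] = y[:, 0 * c:1 * c]
    out[:, :, 1::2, 0::2] = y[:, 1 * c:2 * c]
    out[:, :, 0::2, 1::2] = y[:, 2 * c:3 * c]
    out[:, :, 1::2, 1::2] = y[:, 3 * c:4 * c]
    return out


class DualBranchFeatureMixer(Module):
    """One full DBFM stage: branches -> fuse -> +input -> space-to-depth ->
    1x1 channel mix -> trailing C2F.  Halves spatial dims."""

    def __init__(self, spec: DbfmSpec, rng=None):
        super().__init__()
        c, cout = spec.in_channels, spec.out_channels
        self.spec = spec
        self.local = C2F(c, c, n=spec.local_repeats, shortcut=True,
                         hidden=spec.local_hidden or c // 2, rng=rng)
        self.global_branch = GlobalInformationBranch(c, spec.dw_kernel, rng=rng)
        self.fuse = ConvBNSiLU(2 * c, c, 1, rng=rng)
        self.mix = ConvBNSiLU(4 * c, cout, 1, rng=rng)
        self.out_c2f = C2F(cout, cout, n=spec.out_repeats, shortcut=True,
                           hidden=spec.out_hidden or cout // 2, rng=rng)

    def fuse_dual_branch(self, ld: Tensor, gi: Tensor) -> Tensor:
        if ld.shape[2:] != gi.shape[2:]:
            raise ValueError("local and global maps must share spatial dims")
        return self.fuse(ag.concat([ld, gi], axis=1))

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[2] % 2 or f.shape[3] % 2:
            raise ValueError("DBFM requires even input spatial dims")
        ld = self.local(f)
        gi = self.global_branch(f)
        fd = self.fuse_dual_branch(ld, gi) + f
        return self.out_c2f(self.mix(space_to_depth(fd)))

    def profile(self, h, w):
        f = self.local.profile(h, w)[0]
        f += self.global_branch.profile(h, w)[0]
        f += self.fuse.profile(h, w)[0]
        f += self.mix.profile(h // 2, w // 2)[0]
        f += self.out_c2f.profile(h // 2, w // 2)[0]
        return f, (h // 2, w // 2)
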