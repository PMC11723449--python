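"""Reusable convolutional blocks: Conv-BN-SiLU, C2F, SPPF, depthwise conv.

These are the YOLO-family primitives the detector's backbone, neck and the
dual-branch mixer are assembled from.  All blocks validate their channel
contracts and, like every layer here, can profile themselves analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module, ModuleList


@dataclass(frozen=True)
class BlockSpec:
    """Shape contract for a conv block."""
    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    n_repeats: int = 1
    shortcut: bool = True

    def __post_init__(self):
        if self.kernel not in (1, 3, 5):
            raise ValueError(f"kernel must be 1, 3 or 5, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


class ConvBNSiLU(Module):
    """Convolution -> batch norm -> SiLU, the basic unit of the network."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, stride, bias=False, groups=groups, rng=rng)
        self.bn = BatchNorm2d(c_out)

    @classmethod
    def from_spec(cls, spec: BlockSpec, rng=None):
        return cls(spec.in_channels, spec.out_channels, spec.kernel, spec.stride, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(self.bn(self.conv(x)))

    def profile(self, h, w):
        return self.conv.profile(h, w)


class Bottleneck(Module):
    """Two 3x3 convs with a residual add when shapes permit (YOLOv8 style).

    `hidden` is the width of the intermediate map; shortcut applies only
    when in == out channels.
    """

    def __init__(self, c_in, c_out, hidden=None, shortcut=True, rng=None):
        super().__init__()
        hidden = hidden or c_out
        self.cv1 = ConvBNSiLU(c_in, hidden, 3, rng=rng)
        self.cv2 = ConvBNSiLU(hidden, c_out, 3, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, h, w):
        f1, _ = self.cv1.profile(h, w)
        f2, _ = self.cv2.profile(h, w)
        return f1 + f2, (h, w)


class C2F(Module):
    """CSP-with-2-convolutions block: 1x1 expand, split, n bottlenecks whose
    outputs are all concatenated, 1x1 fuse.

    `hidden` defaults to out_channels // 2 (the conventional 0.5 split) but
    is exposed because the mixer stages use calibrated widths.
    """

    def __init__(self, c_in, c_out, n=1, shortcut=True, hidden=None, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError("C2F requires n >= 1 bottlenecks")
        self.hidden = hidden or c_out // 2
        self.n = n
        self.cv1 = ConvBNSiLU(c_in, 2 * self.hidden, 1, rng=rng)
        self.cv2 = ConvBNSiLU((2 + n) * self.hidden, c_out, 1, rng=rng)
        self.m = ModuleList(
            Bottleneck(self.hidden, self.hidden, hidden=self.hidden, shortcut=shortcut, rng=rng)
            for _ in range(n)
        )

    @classmethod
    def from_spec(cls, spec: BlockSpec, rng=None):
        return cls(spec.in_channels, spec.out_channels, spec.n_repeats,
                   spec.shortcut, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        h = self.hidden
        parts = [y[:, :h], y[:, h:]]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(ag.concat(parts, axis=1))

    def profile(self, h, w):
        f, _ = self.cv1.profile(h, w)
        for m in self.m:
            fm, _ = m.profile(h, w)
            f += fm
        f += self.cv2.profile(h, w)[0]
        return f, (h, w)


class SPPF(Module):
    """Spatial pyramid pooling (fast): 1x1 squeeze, three cascaded max-pools,
    concat of all four maps, 1x1 fuse.  Spatial dims are preserved."""

    def __init__(self, c_in, c_out, pool_kernel=5, rng=None):
        super().__init__()
        if pool_kernel % 2 == 0 or pool_kernel < 3:
            raise ValueError("pool kernel must be odd and >= 3")
        c = c_in // 2
        self.k = pool_kernel
        self.cv1 = ConvBNSiLU(c_in, c, 1, rng=rng)
        self.cv2 = ConvBNSiLU(4 * c, c_out, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        p = self.k // 2
        y1 = ag.maxpool2d(y, self.k, 1, p)
        y2 = ag.maxpool2d(y1, self.k, 1, p)
        y3 = ag.maxpool2d(y2, self.k, 1, p)
        return self.cv2(ag.concat([y, y1, y2, y3], axis=1))

    def profile(self, h, w):
        return self.cv1.profile(h, w)[0] + self.cv2.profile(h, w)[0], (h, w)


def count_parameters(module: Module) -> int:
    """Number of trainable scalars in a module."""
    return module.num_parameters()
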