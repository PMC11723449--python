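"""Layer/module abstractions over the autograd engine.

Modules own `Tensor` parameters, discover submodules by attribute scanning,
and carry a `training` flag.  Each leaf layer also knows how to profile
itself analytically: `profile(h, w)` returns the conv/linear FLOPs it would
execute on an h x w input (1 multiply-accumulate = 2 FLOPs; normalisation,
pooling and activations are excluded, matching how single-stage detector
budgets are conventionally reported) together with the output spatial size.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield f"{name}.{i}", m

    def modules(self):
        yield self
        for _, c in self.children():
            yield from c.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (f"{prefix}{name}", v)
        for name, c in self.children():
            yield from c.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield (f"{prefix}{name}", v)
        for name, c in self.children():
            yield from c.buffers(f"{prefix}{name}.")

    # -- state ------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {f"p:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"b:{k}": v for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[f"p:{k}"], dtype=np.float32)
        for k, b in self.buffers():
            b[...] = state[f"b:{k}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- profiling --------------------------------------------------------
    def profile(self, h: int, w: int):
        """(flops, (h_out, w_out)) for an input of spatial size h x w."""
        raise NotImplementedError(type(self).__name__)


class ModuleList(list):
    pass


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Plain convolution (optionally depthwise via groups=in_channels)."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=None, bias=True,
                 groups=1, rng: np.random.Generator | None = None):
        super().__init__()
        if groups != 1:
            if groups != c_in:
                raise ValueError("only groups=1 or depthwise groups are supported")
            if c_out != c_in:
                raise ValueError("depthwise conv requires c_out == c_in")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (c_out, c_in // groups, kernel, kernel), fan_in))
        self.weight.requires_grad = True
        self.bias = None
        if bias:
            self.bias = Tensor(np.zeros(c_out, dtype=np.float32))
            self.bias.requires_grad = True

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        if self.stride == 2 and (x.shape[2] % 2 or x.shape[3] % 2):
            raise ValueError("stride-2 conv requires even spatial dims")
        if self.groups == 1:
            return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def profile(self, h, w):
        ho = (h + 2 * self.padding - self.kernel) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel) // self.stride + 1
        macs = self.weight.data.size * ho * wo
        return 2 * macs, (ho, wo)


class BatchNorm2d(Module):
    """Batch normalisation with YOLO-family defaults (eps 1e-3, momentum 0.03)."""

    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Tensor(np.ones(c, dtype=np.float32))
        self.weight.requires_grad = True
        self.bias = Tensor(np.zeros(c, dtype=np.float32))
        self.bias.requires_grad = True
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def identity_(self):
        """Make the layer an exact identity in eval mode (for hand oracles)."""
        self.weight.data[:] = 1.0
        self.bias.data[:] = 0.0
        self.running_mean[:] = 0.0
        self.running_var[:] = 1.0 - self.eps
        return self

    def forward(self, x: Tensor) -> Tensor:
        shp = (1, self.c, 1, 1)
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = v.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (m.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            xn = xc * ((v + self.eps) ** -0.5)
        else:
            xn = (x - self.running_mean.reshape(shp)) * \
                 (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shp)
        return xn * self.weight.reshape(shp) + self.bias.reshape(shp)

    def profile(self, h, w):
        return 0, (h, w)


class Upsample2x(Module):
    def forward(self, x):
        return ag.upsample2x(x)

    def profile(self, h, w):
        return 0, (h * 2, w * 2)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def profile(self, h, w):
        flops = 0
        for m in self.mods:
            f, (h, w) = m.profile(h, w)
            flops += f
        return flops, (h, w)
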