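"""Building blocks: the GRN-GELU Conv module, the downsample layer, the stem.

The GRN-GELU Conv module is a depthwise-separable residual block:

    y = GELU( x + pw( GELU( GRN( dw(x) ) ) ) )

where dw is a depthwise 3x3 convolution (one filter per channel, biased),
GRN is global response normalization, and pw is a biased 1x1 pointwise
convolution with equal input and output channels. GELU is the exact
erf-based form throughout. Per module the trainable count is
C^2 + 13C  (pointwise C^2 + C, depthwise 9C + C, GRN 2C).

The downsample layer is a bare biased 2x2 stride-2 convolution that
doubles the channels (8C^2 + 2C parameters) and halves each spatial
dimension with floor semantics. The stem is a bias-free 3->C0 convolution
(k=3, s=2, p=1) followed by GRN and GELU.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Module, Parameter, Tensor, conv2d, he_trunc_normal
from .grn import GRNLayer

__all__ = ["GGEConvModule", "Downsample", "Stem"]





class GGEConvModule(Module):
    """Depthwise 3x3 -> GRN -> GELU -> pointwise 1x1 -> residual -> GELU."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.dw_kernel = Parameter(he_trunc_normal(rng, (channels, 1, 3, 3)), dtype=dtype)
        self.dw_bias = Parameter(np.zeros(channels), dtype=dtype)
        self.grn = GRNLayer(channels, dtype=dtype)
        self.pw_kernel = Parameter(he_trunc_normal(rng, (channels, channels, 1, 1)),
                                   dtype=dtype)
        self.pw_bias = Parameter(np.zeros(channels), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        h = conv2d(x, self.dw_kernel, self.dw_bias, padding=1, groups=self.channels)
        h = self.grn(h).gelu()
        h = conv2d(h, self.pw_kernel, self.pw_bias)
        return (x + h).gelu()


class Downsample(Module):
    """2x2 stride-2 biased convolution, C -> 2C channels."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        # no activation follows this conv, so variance-preserving gain 1
        self.kernel = Parameter(
            he_trunc_normal(rng, (2 * channels, channels, 2, 2), gain=1.0),
            dtype=dtype)
        self.bias = Parameter(np.zeros(2 * channels), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} too small to downsample")
        return conv2d(x, self.kernel, self.bias, stride=2)


class Stem(Module):
    """Bias-free 3->C0 conv (k=3, s=2, p=1), then GRN and GELU."""

    def __init__(self, out_channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.out_channels = out_channels
        self.kernel = Parameter(he_trunc_normal(rng, (out_channels, 3, 3, 3)), dtype=dtype)
        self.grn = GRNLayer(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(f"stem expects 3-channel RGB input, got {x.shape[1]}")
        h = conv2d(x, self.kernel, stride=2, padding=1)
        return self.grn(h).gelu()
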