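"""Channel + spatial attention (convolutional block attention, CBAM style).

Channel attention squeezes the feature map with global average and global
max pooling, pushes both descriptors through a shared bias-free two-layer
MLP with a reduction bottleneck, sums them and gates the channels with a
sigmoid. Spatial attention pools over channels (mean and max), stacks the
two maps, convolves them with a single bias-free k x k filter and gates
positions with a sigmoid. The attention module applies the two gates
sequentially: ``out = SA(CA(x))``. Its output tensor is the "attention
map" that the distillation stage matches between teacher and student.

The gate-product form ``out_s(x) * (out_c(x) * x)``, in which the spatial
gate is computed on the raw input rather than on the channel-gated one,
is kept available behind ``sequential=False`` for comparison; the
sequential composition is the default and the one used by the networks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Module, Parameter, Tensor, concat, conv2d,
                       he_trunc_normal)

__all__ = ["ChannelAttention", "SpatialAttention", "AttentionModule",
           "channel_attention", "spatial_attention", "attention_module"]





class ChannelAttention(Module):
    """Per-channel sigmoid gate from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        if channels % reduction != 0:
            raise ValueError(
                f"reduction ratio {reduction} must divide channel count {channels}")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.channels = channels
        self.reduction = reduction
        # shared between the avg- and max-pooled branches; no biases
        self.w1 = Parameter(he_trunc_normal(rng, (hidden, channels)), dtype=dtype)
        self.w2 = Parameter(he_trunc_normal(rng, (channels, hidden)), dtype=dtype)

    def gate(self, x: Tensor) -> Tensor:
        """The pre-broadcast sigmoid gate, shape (N, C, 1, 1)."""
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        x_avg = x.mean(axis=(2, 3))              # (N, C)
        x_max = x.max(axis=(2, 3))               # (N, C)
        z = self._mlp(x_max) + self._mlp(x_avg)
        n, c = z.shape
        return z.sigmoid().reshape(n, c, 1, 1)

    def _mlp(self, v: Tensor) -> Tensor:
        return (v @ self.w1.transpose2d()).relu() @ self.w2.transpose2d()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialAttention(Module):
    """Position-wise sigmoid gate from channel-pooled maps through one conv."""

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        if kernel_size % 2 != 1:
            raise ValueError("spatial kernel size must be odd to preserve shape")
        rng = rng or np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2
        # 2 input channels (avg, max), 1 output channel, no bias
        self.kernel = Parameter(
            he_trunc_normal(rng, (1, 2, kernel_size, kernel_size)), dtype=dtype)

    def gate(self, x: Tensor) -> Tensor:
        """The sigmoid gate, shape (N, 1, H, W)."""
        x_avg = x.mean(axis=1, keepdims=True)    # (N, 1, H, W)
        x_max = x.max(axis=1, keepdims=True)
        stacked = concat([x_avg, x_max], axis=1)  # (N, 2, H, W)
        return conv2d(stacked, self.kernel, padding=self.padding).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class AttentionModule(Module):
    """Channel then spatial attention; the output is the distilled map."""

    def __init__(self, channels: int, reduction: int = 16, kernel_size: int = 7,
                 sequential: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, reduction, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(kernel_size, rng=rng, dtype=dtype)
        self.sequential = sequential

    def forward(self, x: Tensor) -> Tensor:
        u = self.channel(x)
        if self.sequential:
            return self.spatial(u)
        # literal gate-product variant: spatial gate computed on the raw input
        return self.spatial.gate(x) * u


# Functional forms used by the tests and the oracle comparisons ---------------
def channel_attention(x, module: ChannelAttention) -> np.ndarray:
    out = module(Tensor(np.asarray(x)))
    return out.data


def spatial_attention(x, module: SpatialAttention) -> np.ndarray:
    out = module(Tensor(np.asarray(x)))
    return out.data


def attention_module(x, module: AttentionModule) -> np.ndarray:
    out = module(Tensor(np.asarray(x)))
    return out.data
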