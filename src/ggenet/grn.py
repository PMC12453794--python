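"""Global response normalization (GRN).

GRN rescales each channel of a feature map by the ratio of its spatial
L2 norm to the mean of those norms across channels, with a learnable
per-channel gain and shift and a residual pass-through:

    G_c = sqrt( sum_{i,j} x_{c,i,j}^2 )          (per sample, per channel)
    N_c = G_c / ( mean_c G + 1e-6 )
    y   = gamma_c * (x * N_c) + beta_c + x

With gamma = beta = 0 the layer is exactly the identity, which is also
its initialization, so a fresh network starts with GRN transparent.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Module, Parameter, Tensor

__all__ = ["GRNLayer", "grn_forward", "grn_forward_array", "EPSILON"]

EPSILON = 1e-6  # stabilizer in the channel-mean denominator; never trained


def grn_forward(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = EPSILON) -> Tensor:
    """GRN on an autodiff tensor x of shape (N, C, H, W).

    gamma/beta hold one value per channel (any shape of size C).
    """
    if x.ndim != 4:
        raise ValueError(f"expected a 4-d (N, C, H, W) tensor, got ndim={x.ndim}")
    c = x.shape[1]
    if gamma.data.size != c or beta.data.size != c:
        raise ValueError(
            f"channel mismatch: x has {c} channels, gamma/beta have "
            f"{gamma.data.size}/{beta.data.size} entries")
    g = (x * x).sum(axis=(2, 3), keepdims=True).sqrt()          # (N, C, 1, 1)
    n = g / (g.mean(axis=1, keepdims=True) + eps)               # (N, C, 1, 1)
    gamma4 = gamma.reshape(1, c, 1, 1)
    beta4 = beta.reshape(1, c, 1, 1)
    return gamma4 * (x * n) + beta4 + x


def grn_forward_array(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                      eps: float = EPSILON) -> np.ndarray:
    """Convenience wrapper: GRN on plain arrays, no gradient tracking."""
    out = grn_forward(Tensor(np.asarray(x)),
                      Tensor(np.asarray(gamma)),
                      Tensor(np.asarray(beta)), eps=eps)
    return out.data


class GRNLayer(Module):
    """GRN with learnable per-channel gamma/beta, both zero-initialized."""

    def __init__(self, channels: int, dtype=np.float64):
        if channels < 1:
            raise ValueError("channels must be >= 1")
        self.channels = channels
        self.gamma = Parameter(np.zeros(channels), dtype=dtype)
        self.beta = Parameter(np.zeros(channels), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return grn_forward(x, self.gamma, self.beta)
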