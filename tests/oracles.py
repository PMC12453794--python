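"""Naive loop-based reference implementations used as independent oracles.

Everything here is written with explicit python loops over batch,
channel and spatial indices, directly from the layer definitions, and is
deliberately independent of the vectorized implementations it checks.
"""

import math

import numpy as np


def gelu_ref(x: float) -> float:
    return x * 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def sigmoid_ref(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def grn_ref(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
            eps: float = 1e-6) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        g = np.zeros(c)
        for ch in range(c):
            acc = 0.0
            for i in range(h):
                for j in range(w):
                    acc += x[b, ch, i, j] ** 2
            g[ch] = math.sqrt(acc)
        g_mean = g.sum() / c
        for ch in range(c):
            nx = g[ch] / (g_mean + eps)
            for i in range(h):
                for j in range(w):
                    v = x[b, ch, i, j]
                    out[b, ch, i, j] = gamma[ch] * (v * nx) + beta[ch] + v
    return out


def channel_attention_ref(x: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        x_avg = np.array([x[b, ch].mean() for ch in range(c)])
        x_max = np.array([x[b, ch].max() for ch in range(c)])
        z = np.zeros(c)
        for v in (x_max, x_avg):
            hidden = np.maximum(w1 @ v, 0.0)
            z += w2 @ hidden
        for ch in range(c):
            out[b, ch] = x[b, ch] * sigmoid_ref(z[ch])
    return out


def spatial_attention_ref(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """kernel shape (1, 2, k, k); zero padding k//2 keeps the spatial size."""
    n, c, h, w = x.shape
    k = kernel.shape[2]
    pad = k // 2
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        pooled = np.stack([x[b].mean(axis=0), x[b].max(axis=0)])  # (2, H, W)
        padded = np.zeros((2, h + 2 * pad, w + 2 * pad))
        padded[:, pad:pad + h, pad:pad + w] = pooled
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for ch2 in range(2):
                    for a in range(k):
                        for bb in range(k):
                            acc += padded[ch2, i + a, j + bb] * kernel[0, ch2, a, bb]
                gate = sigmoid_ref(acc)
                for ch in range(c):
                    out[b, ch, i, j] = x[b, ch, i, j] * gate
    return out


def depthwise3x3_ref(x: np.ndarray, w: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """w shape (C, 1, 3, 3), zero padding 1."""
    n, c, h, wd = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                for j in range(wd):
                    acc = bias[ch]
                    for a in range(3):
                        for bb in range(3):
                            ii, jj = i + a - 1, j + bb - 1
                            if 0 <= ii < h and 0 <= jj < wd:
                                acc += x[b, ch, ii, jj] * w[ch, 0, a, bb]
                    out[b, ch, i, j] = acc
    return out


def gge_conv_ref(x, dw_w, dw_b, gamma, beta, pw_w, pw_b) -> np.ndarray:
    n, c, h, wd = x.shape
    hidden = depthwise3x3_ref(x, dw_w, dw_b)
    hidden = grn_ref(hidden, gamma, beta)
    hidden = np.vectorize(gelu_ref)(hidden)
    out = np.zeros_like(x, dtype=float)
    for b in range(n):
        for co in range(c):
            for i in range(h):
                for j in range(wd):
                    acc = pw_b[co]
                    for ci in range(c):
                        acc += hidden[b, ci, i, j] * pw_w[co, ci, 0, 0]
                    out[b, co, i, j] = acc
    return np.vectorize(gelu_ref)(x + out)
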