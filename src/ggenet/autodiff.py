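"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free, graph-based engine in the micrograd style, extended to
n-dimensional arrays with full broadcasting support and the handful of
operations the GGENet family needs: strided/grouped 2-D convolution,
axis reductions (sum / mean / max), the exact erf-based GELU, sigmoid,
ReLU, concatenation and a numerically stable softmax cross-entropy.

Every `Tensor` wraps one ndarray; calling :meth:`Tensor.backward` on a
scalar runs a topological sweep and accumulates ``.grad`` on every
reachable tensor with ``requires_grad=True``. Gradients of every op are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "Module", "Adam", "gelu_scalar", "no_grad",
           "he_trunc_normal"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _ensure_tensor(obj) -> "Tensor":
    return obj if isinstance(obj, Tensor) else Tensor(obj)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        # fresh-array contract: every backward closure hands over an array it
        # does not mutate afterwards, so the first accumulation can alias it
        self.grad = g if self.grad is None else self.grad + g

    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars at the tensor's dtype: no silent float64 upcast
        if isinstance(other, (int, float)) and self.data.dtype.kind == "f":
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[0] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims: bool = False):
        """Max over `axis`; ties share the gradient equally."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded).astype(self.data.dtype)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ nonlinearity
    def relu(self):
        out_data = np.maximum(self.data, 0)

        def backward(g):
            self._accumulate(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        # tanh form is overflow-free at both tails
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        """Exact Gaussian error linear unit, x * Phi(x) with the erf form."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        out_data = x * phi

        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            self._accumulate(g * (phi + x * pdf))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            # subgradient 0 where the input is exactly zero (all-zero channels)
            denom = 2.0 * out_data
            self._accumulate(g * np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------- free functions
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    ref = tensors[0]
    return ref._make(out_data, tuple(tensors), backward)


def _conv_windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (N, C, Ho, Wo, kh, kw) of `x`; no copy."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation; supports groups=1 (dense) and groups=C (depthwise).

    weight: (Cout, Cin/groups, kh, kw); bias: (Cout,) or None.
    """
    x = _ensure_tensor(x)
    weight = _ensure_tensor(weight)
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    depthwise = groups > 1
    if depthwise and groups != cin:
        raise ValueError(f"unsupported groups={groups} for Cin={cin}")
    if not depthwise and cin_g != cin:
        raise ValueError(f"weight expects {cin_g} input channels, got {cin}")
    if depthwise and (cin_g != 1 or cout != cin):
        raise ValueError("depthwise conv requires weight shape (C, 1, kh, kw)")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ValueError(
            f"spatial size {xp.shape[2]}x{xp.shape[3]} smaller than kernel {kh}x{kw}")
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1

    # three code paths, all BLAS-backed where it matters:
    # pointwise 1x1 as a batched matmul, depthwise on strided windows,
    # dense via im2col.
    if not depthwise and kh == 1 and kw == 1 and stride == 1:
        x2 = xp.reshape(n, cin, hp * wp)
        wm = weight.data.reshape(cout, cin)
        out_data = np.matmul(wm, x2).reshape(n, cout, hp, wp)
        mode = "pointwise"
        col = None
    elif depthwise:
        # depthwise as kh*kw shifted multiply-adds; faster than windowed einsum
        wd = weight.data[:, 0]
        out_data = np.zeros((n, cin, ho, wo), dtype=np.result_type(xp, wd))
        for a in range(kh):
            for b in range(kw):
                out_data += xp[:, :, a:a + stride * ho:stride,
                               b:b + stride * wo:stride] * wd[:, a, b][None, :, None, None]
        mode = "depthwise"
        col = None
    else:
        win = _conv_windows(xp, kh, kw, stride)
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * kh * kw)
        wm = weight.data.reshape(cout, cin * kh * kw)
        out_data = (col @ wm.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
        mode = "dense"
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        g = np.ascontiguousarray(g)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if mode == "pointwise":
            g2 = g.reshape(n, cout, hp * wp)
            x2b = xp.reshape(n, cin, hp * wp)
            if weight.requires_grad:
                gw = np.tensordot(g2, x2b, axes=([0, 2], [0, 2]))
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                wm2 = weight.data.reshape(cout, cin)
                x._accumulate(np.matmul(wm2.T, g2).reshape(n, cin, hp, wp))
            return
        if weight.requires_grad:
            if mode == "depthwise":
                gw = np.empty((cin, 1, kh, kw), dtype=g.dtype)
                for a in range(kh):
                    for b in range(kw):
                        sl = xp[:, :, a:a + stride * ho:stride,
                                b:b + stride * wo:stride]
                        gw[:, 0, a, b] = (sl * g).sum(axis=(0, 2, 3))
            else:
                gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
                gw = (gm.T @ col).reshape(weight.shape)
            weight._accumulate(gw)
        if x.requires_grad:
            gx_pad = np.zeros((n, cin, hp, wp), dtype=g.dtype)
            if mode == "depthwise":
                for a in range(kh):
                    for b in range(kw):
                        contrib = g * weight.data[:, 0, a, b][None, :, None, None]
                        gx_pad[:, :, a:a + stride * ho:stride,
                               b:b + stride * wo:stride] += contrib
            else:
                gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
                wm2 = weight.data.reshape(cout, cin * kh * kw)
                gcol = (gm @ wm2).reshape(n, ho, wo, cin, kh, kw)
                for a in range(kh):
                    for b in range(kw):
                        gx_pad[:, :, a:a + stride * ho:stride,
                               b:b + stride * wo:stride] += \
                            gcol[:, :, :, :, a, b].transpose(0, 3, 1, 2)
            if padding:
                gx_pad = gx_pad[:, :, padding:hp - padding, padding:wp - padding]
            x._accumulate(gx_pad)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return x._make(out_data, parents, backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x (N, Cin) @ weight.T (Cin, Cout) + bias."""
    out = x @ _ensure_tensor(weight).transpose2d()
    if bias is not None:
        out = out + bias
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy (nats) of integer `labels` under softmax(logits)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -(np.log(p[np.arange(n), labels] + 1e-300)).mean()

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return logits._make(np.asarray(nll), (logits,), backward)


def log_softmax(logits: Tensor) -> Tensor:
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    out_data = z - lse
    p = np.exp(out_data)

    def backward(g):
        logits._accumulate(g - p * g.sum(axis=1, keepdims=True))

    return logits._make(out_data, (logits,), backward)


def kd_kl_divergence(student_logits: Tensor, teacher_logits: np.ndarray,
                     tau: float) -> Tensor:
    """Temperature-softened KL(p_T || p_S), scaled by tau^2, batch mean."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    t = np.asarray(teacher_logits) / tau
    t = t - t.max(axis=1, keepdims=True)
    pt = np.exp(t)
    pt /= pt.sum(axis=1, keepdims=True)
    log_ps = log_softmax(student_logits * (1.0 / tau))
    ent_t = float((pt * np.log(pt + 1e-300)).sum(axis=1).mean())
    cross = (Tensor(pt) * log_ps).sum(axis=1).mean()
    return (ent_t - cross) * (tau * tau)


# --------------------------------------------------------------------- modules
def _transpose2d(self: Tensor) -> Tensor:
    def backward(g):
        self._accumulate(g.T)

    return self._make(self.data.T, (self,), backward)


Tensor.transpose2d = _transpose2d


class Parameter(Tensor):
    """A trainable leaf tensor (float64 unless a dtype is given)."""

    def __init__(self, data, dtype=np.float64):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


class Module:
    """Tiny nn container: tracks Parameters and sub-Modules by attribute."""

    def parameters(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def he_trunc_normal(rng: np.random.Generator, shape, fan_in: int | None = None,
                     gain: float = 2.0) -> np.ndarray:
    """Fan-in-scaled truncated normal (+/- 2 sd): keeps activation variance
    stable through deep stacks without normalization rescue."""
    if fan_in is None:
        fan_in = int(np.prod(shape[1:]))
    std = math.sqrt(gain / fan_in)
    return np.clip(rng.standard_normal(shape) * std, -2 * std, 2 * std)


def gelu_scalar(x: float) -> float:
    """Exact GELU on a python float (reference for tests and docs)."""
    return x * 0.5 * (1.0 + math.erf(x / _SQRT2))
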