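"""Adaptive knowledge distillation: logit-based and attention-map-based.

Logit mode follows the classic teacher/student recipe with a dynamic
mixing weight: per batch,

    alpha      = loss_CE / (loss_CE + loss_distill)
    loss_total = (1 - alpha) * loss_CE + alpha * loss_distill

where loss_distill is the temperature-softened KL divergence between the
teacher's and student's class distributions. Substituting alpha gives
the harmonic-mean identity loss_total = 2ab / (a + b).

Attention mode (the headline variant) matches the three attention-module
output tensors. A bank of three 1x1 adapters projects the student maps
up to the teacher's channel counts; the hidden loss is the mean of the
three per-map MSEs, and its weight is the loss ratio clamped to
[0.25, 0.75]:

    w          = clamp( loss_hidden / (loss_hidden + loss_CE), 0.25, 0.75 )
    loss_total = w * loss_hidden + (1 - w) * loss_CE

Both dynamic weights are treated as detached scalars: they steer the
loss mix but no gradient flows through them. The teacher is frozen;
gradients reach only the student and the adapters, which are discarded
at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Adam, Module, Parameter, Tensor, conv2d,
                       he_trunc_normal, kd_kl_divergence, no_grad,
                       softmax_cross_entropy)
from .model import GGENet

__all__ = ["KDConfig", "AdapterBank", "DistillLossBreakdown",
           "soft_targets", "adaptive_alpha", "logit_kd_total",
           "hidden_loss", "hidden_weight", "attention_kd_total",
           "distill_step", "distill_train",
           "HIDDEN_WEIGHT_MIN", "HIDDEN_WEIGHT_MAX"]

HIDDEN_WEIGHT_MIN = 0.25
HIDDEN_WEIGHT_MAX = 0.75


@dataclass
class KDConfig:
    mode: str = "attention"          # "attention" or "logit"
    temperature: float = 4.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mode not in ("attention", "logit"):
            raise ValueError(f"unknown distillation mode {self.mode!r}")


@dataclass
class DistillLossBreakdown:
    """Per-step record of the loss components and the dynamic weight."""

    loss_ce: float
    loss_distill: float              # KL term (logit mode) or hidden MSE term
    weight: float                    # alpha (logit) or weight_hidden (attention)
    loss_total: float


# ----------------------------------------------------------- scalar algebra
def soft_targets(logits: np.ndarray, tau: float) -> np.ndarray:
    """softmax(logits / tau) along the last axis; higher tau flattens."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=float) / tau
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def adaptive_alpha(loss_ce: float, loss_distill: float) -> float:
    """Dynamic mixing weight; 0.5 in the doubly-degenerate all-zero case."""
    if loss_ce < 0 or loss_distill < 0:
        raise ValueError("loss values must be non-negative")
    if loss_ce == 0 and loss_distill == 0:
        return 0.5
    return loss_ce / (loss_ce + loss_distill)


def logit_kd_total(loss_ce: float, loss_distill: float) -> float:
    alpha = adaptive_alpha(loss_ce, loss_distill)
    return (1.0 - alpha) * loss_ce + alpha * loss_distill


def hidden_weight(loss_hidden: float, loss_ce: float) -> float:
    """Loss-ratio weight for the hidden term, clamped to [0.25, 0.75]."""
    if loss_hidden < 0 or loss_ce < 0:
        raise ValueError("loss values must be non-negative")
    if loss_hidden == 0 and loss_ce == 0:
        raw = 0.5
    else:
        raw = loss_hidden / (loss_hidden + loss_ce)
    return float(np.clip(raw, HIDDEN_WEIGHT_MIN, HIDDEN_WEIGHT_MAX))


def attention_kd_total(loss_hidden: float, loss_ce: float) -> float:
    w = hidden_weight(loss_hidden, loss_ce)
    return w * loss_hidden + (1.0 - w) * loss_ce


# --------------------------------------------------------------- adapters
class AdapterBank(Module):
    """Three biased 1x1 convs projecting student map channels up to teacher's."""

    def __init__(self, student_channels, teacher_channels, seed: int = 0,
                 dtype=np.float64):
        if len(student_channels) != 3 or len(teacher_channels) != 3:
            raise ValueError("expected three attention depths")
        rng = np.random.default_rng(seed)
        self.student_channels = tuple(student_channels)
        self.teacher_channels = tuple(teacher_channels)
        self.adapters = []
        for cs, ct in zip(student_channels, teacher_channels):
            w = he_trunc_normal(rng, (ct, cs, 1, 1), gain=1.0)
            self.adapters.append(_Adapter(w, ct, dtype))

    @classmethod
    def for_models(cls, teacher: GGENet, student: GGENet, seed: int = 0,
                   dtype=np.float64) -> "AdapterBank":
        return cls(student.spec.attention_channels(),
                   teacher.spec.attention_channels(), seed=seed, dtype=dtype)

    def project(self, student_maps) -> list:
        if len(student_maps) != 3:
            raise ValueError("expected three student attention maps")
        out = []
        for m, adapter, cs in zip(student_maps, self.adapters, self.student_channels):
            m = m if isinstance(m, Tensor) else Tensor(np.asarray(m))
            if m.shape[1] != cs:
                raise ValueError(
                    f"adapter expects {cs} student channels, got {m.shape[1]}")
            out.append(adapter(m))
        return out


class _Adapter(Module):
    def __init__(self, w, ct, dtype):
        self.weight = Parameter(w, dtype=dtype)
        self.bias = Parameter(np.zeros(ct), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


def hidden_loss(student_maps, teacher_maps, adapters: AdapterBank) -> Tensor:
    """Mean of the three per-map MSEs on adapter-projected student maps."""
    projected = adapters.project(student_maps)
    total = None
    for p, t in zip(projected, teacher_maps):
        t = t if isinstance(t, Tensor) else Tensor(np.asarray(t))
        if p.shape != t.shape:
            raise ValueError(
                f"adapted student map {p.shape} does not match teacher map {t.shape}")
        diff = p - t.detach()
        mse = (diff * diff).mean()
        total = mse if total is None else total + mse
    return total * (1.0 / 3.0)


# ------------------------------------------------------------- training step
def distill_step(teacher: GGENet, student: GGENet, adapters: AdapterBank | None,
                 batch, optimizer: Adam, config: KDConfig) -> DistillLossBreakdown:
    """One optimization step on the student (and adapters); teacher frozen.

    `batch` is (images, labels) with images (N, 3, H, W) and integer labels.
    """
    x, y = batch
    x = np.asarray(x)
    y = np.asarray(y)
    if config.mode == "attention":
        if adapters is None:
            raise ValueError("attention mode requires an AdapterBank")
        with no_grad():  # teacher frozen; no graph built
            t_logits, t_maps = teacher.forward(Tensor(x), capture_attention=True)
        t_maps = [m.detach() for m in t_maps]
        s_logits, s_maps = student.forward(Tensor(x), capture_attention=True)
        ce = softmax_cross_entropy(s_logits, y)
        hid = hidden_loss(s_maps, t_maps, adapters)
        w = hidden_weight(hid.item(), ce.item())           # detached scalar
        total = w * hid + (1.0 - w) * ce
        breakdown = DistillLossBreakdown(ce.item(), hid.item(), w, total.item())
    else:
        with no_grad():
            t_logits = teacher.forward(Tensor(x))
        s_logits = student.forward(Tensor(x))
        ce = softmax_cross_entropy(s_logits, y)
        kl = kd_kl_divergence(s_logits, t_logits.data, config.temperature)
        kl_val = max(kl.item(), 0.0)   # rounding can push KL ~ 0 below zero
        alpha = adaptive_alpha(ce.item(), kl_val)          # detached scalar
        total = (1.0 - alpha) * ce + alpha * kl
        breakdown = DistillLossBreakdown(ce.item(), kl_val, alpha, total.item())

    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return breakdown


def distill_train(teacher: GGENet, student: GGENet, adapters: AdapterBank | None,
                  x_all: np.ndarray, labels: np.ndarray, train_idx, val_idx,
                  config: KDConfig, epochs: int, batch_size: int = 16,
                  learning_rate: float = 1e-3, seed: int = 0) -> tuple:
    """Full distillation loop over preprocessed inputs `x_all`.

    Follows the evaluation protocol: tracks validation accuracy per epoch
    and restores the best-validation student state at the end. Returns
    (breakdowns, history) where history holds per-epoch validation
    accuracy.
    """
    params = student.parameters() + (adapters.parameters() if adapters else [])
    optimizer = Adam(params, lr=learning_rate)
    rng = np.random.default_rng(seed)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    breakdowns, history = [], []
    best_acc, best_state = -1.0, None
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            breakdowns.append(distill_step(
                teacher, student, adapters, (x_all[idx], labels[idx]),
                optimizer, config))
        correct = 0
        with no_grad():
            for lo in range(0, len(val_idx), batch_size):
                sel = val_idx[lo:lo + batch_size]
                pred = student.forward(Tensor(x_all[sel])).data.argmax(axis=1)
                correct += int((pred == labels[sel]).sum())
        val_acc = correct / len(val_idx)
        history.append({"epoch": epoch + 1, "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_state = val_acc, student.state_dict()
    if best_state is not None:
        student.load_state_dict(best_state)
    return breakdowns, history
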