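"""Adaptive distillation: scalar algebra, adapters, one full training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ggenet as gg
from ggenet.autodiff import Adam, Tensor
from ggenet.distill import (HIDDEN_WEIGHT_MAX, HIDDEN_WEIGHT_MIN, KDConfig,
                            adaptive_alpha, attention_kd_total, distill_step,
                            hidden_loss, hidden_weight, logit_kd_total,
                            soft_targets)

nonneg = st.one_of(st.just(0.0),
                   st.floats(min_value=1e-9, max_value=1e6))


def test_soft_targets_examples():
    np.testing.assert_allclose(soft_targets(np.array([1.0, 1.0, 1.0]), 2.0),
                               np.full(3, 1 / 3))
    flat = soft_targets(np.array([3.0, -1.0, 0.5]), 1e6)
    assert flat.max() - flat.min() < 1e-3
    p = soft_targets(np.array([2.0, 0.0]), 2.0)
    e = np.e
    np.testing.assert_allclose(p, [e / (e + 1), 1 / (e + 1)], rtol=1e-12)
    assert p.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        soft_targets(np.zeros(3), 0.0)


@pytest.mark.parametrize("ce,distill,expected", [(1, 1, 0.5), (3, 1, 0.75),
                                                 (1, 0, 1.0), (0, 0, 0.5)])
def test_adaptive_alpha_values(ce, distill, expected):
    assert adaptive_alpha(ce, distill) == pytest.approx(expected)


@given(a=nonneg, b=st.floats(min_value=1e-9, max_value=1e6), d=st.floats(
    min_value=1e-9, max_value=1e3))
@settings(max_examples=200, deadline=None)
def test_adaptive_alpha_monotonicity(a, b, d):
    assert adaptive_alpha(a, b + d) <= adaptive_alpha(a, b)
    assert adaptive_alpha(a + d, b) >= adaptive_alpha(a, b)


@given(a=nonneg, b=nonneg)
@settings(max_examples=300, deadline=None)
def test_logit_total_is_harmonic_mean_and_weight_clamped(a, b):
    if a + b > 0:
        # absolute slack scaled by (a+b) absorbs the cancellation error of
        # (1 - alpha) * a when the two losses differ by many orders
        assert logit_kd_total(a, b) == pytest.approx(
            2 * a * b / (a + b), rel=1e-6, abs=1e-11 * (a + b))
    w = hidden_weight(a, b)
    assert HIDDEN_WEIGHT_MIN <= w <= HIDDEN_WEIGHT_MAX


@pytest.mark.parametrize("hid,ce,w", [(1, 1, 0.5), (9, 1, 0.75), (0.01, 0.99, 0.25)])
def test_hidden_weight_clamping(hid, ce, w):
    assert hidden_weight(hid, ce) == pytest.approx(w)


def test_attention_total_examples():
    assert attention_kd_total(5.0, 5.0) == pytest.approx(5.0)
    assert attention_kd_total(9.0, 1.0) == pytest.approx(0.75 * 9 + 0.25 * 1)
    lo, hi = sorted([2.0, 7.0])
    assert lo <= attention_kd_total(2.0, 7.0) <= hi


def _toy_pair(seed=0):
    t = gg.build_model(gg.ModelSpec(base_width=4, attention_r=2, spatial_k=3,
                                    input_size=64), seed=seed, dtype=np.float32)
    s = gg.build_model(gg.ModelSpec(base_width=2, attention_r=2, spatial_k=3,
                                    input_size=64), seed=seed + 1, dtype=np.float32)
    # give both heads small random weights so logits are informative (the
    # fresh zero-initialized head would make both output distributions
    # uniform and the logit-mode divergence identically zero)
    r = np.random.default_rng(seed + 7)
    for net in (t, s):
        net.head.weight.data[:] = r.standard_normal(net.head.weight.shape) * 0.1
    # an untrained toy network emits near-zero logits; give the teacher a
    # clearly non-uniform output distribution as a trained one would have
    t.head.bias.data[:] = r.standard_normal(6)
    return t, s


def test_hidden_loss_zero_for_matching_maps_and_constant_offset(rng):
    t, s = _toy_pair()
    adapters = gg.AdapterBank.for_models(t, s, dtype=np.float32)
    maps_s = [rng.standard_normal((2, c, 4, 4)).astype(np.float32)
              for c in s.spec.attention_channels()]
    projected = [m.data for m in adapters.project([Tensor(m) for m in maps_s])]
    assert hidden_loss(maps_s, projected, adapters).item() == pytest.approx(0.0)
    shifted = [p + 0.5 for p in projected]
    assert hidden_loss(maps_s, shifted, adapters).item() == pytest.approx(0.25,
                                                                          rel=1e-5)


def test_hidden_loss_averages_three_map_mses():
    t, s = _toy_pair()
    adapters = gg.AdapterBank.for_models(t, s, dtype=np.float32)
    maps_s = [np.zeros((1, c, 2, 2), dtype=np.float32)
              for c in s.spec.attention_channels()]
    projected = [m.data for m in adapters.project([Tensor(m) for m in maps_s])]
    # per-map constant offsets d give per-map MSEs d^2: (0.3^2, 0.6^2, 0.9^2)
    offsets = (0.3, 0.6, 0.9)
    teacher_maps = [p + d for p, d in zip(projected, offsets)]
    expected = np.mean([d * d for d in offsets])
    assert hidden_loss(maps_s, teacher_maps, adapters).item() == pytest.approx(
        expected, rel=1e-5)


def test_hidden_loss_shape_mismatch_raises():
    t, s = _toy_pair()
    adapters = gg.AdapterBank.for_models(t, s, dtype=np.float32)
    maps_s = [np.zeros((1, c, 2, 2), dtype=np.float32)
              for c in s.spec.attention_channels()]
    bad_teacher = [np.zeros((1, c, 3, 3), dtype=np.float32)
                   for c in t.spec.attention_channels()]
    with pytest.raises(ValueError, match="match"):
        hidden_loss(maps_s, bad_teacher, adapters)


def test_identity_adapters_on_width_equal_pair_hit_lower_clamp(rng):
    # teacher and student of equal width; identity-initialized square adapters
    t = gg.build_model(gg.ModelSpec(base_width=2, attention_r=2, spatial_k=3,
                                    input_size=64), seed=0, dtype=np.float32)
    s = gg.build_model(gg.ModelSpec(base_width=2, attention_r=2, spatial_k=3,
                                    input_size=64), seed=0, dtype=np.float32)
    adapters = gg.AdapterBank.for_models(t, s, dtype=np.float32)
    for a, c in zip(adapters.adapters, s.spec.attention_channels()):
        a.weight.data[:] = np.eye(c).reshape(c, c, 1, 1)
        a.bias.data[:] = 0.0
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    _, tm = gg.forward_with_attention(t, x)
    _, sm = gg.forward_with_attention(s, x)
    hid = hidden_loss(sm, [m.detach() for m in tm], adapters).item()
    assert hid == pytest.approx(0.0, abs=1e-10)
    assert hidden_weight(hid, 1.3) == HIDDEN_WEIGHT_MIN


@pytest.mark.parametrize("mode", ["attention", "logit"])
def test_distill_step_trains_student_and_freezes_teacher(mode, rng):
    teacher, student = _toy_pair(seed=2)
    adapters = gg.AdapterBank.for_models(teacher, student, dtype=np.float32) \
        if mode == "attention" else None
    params = student.parameters() + (adapters.parameters() if adapters else [])
    opt = Adam(params, lr=2e-3)
    cfg = KDConfig(mode=mode)
    x = rng.standard_normal((8, 3, 64, 64)).astype(np.float32)
    y = rng.integers(0, 6, 8)
    teacher_before = {k: v.copy() for k, v in teacher.state_dict().items()}
    breakdowns = [distill_step(teacher, student, adapters, (x, y), opt, cfg)
                  for _ in range(50)]
    # loss decreases on the fixed batch
    assert breakdowns[-1].loss_total < breakdowns[0].loss_total
    # teacher is bit-identical
    for k, v in teacher.state_dict().items():
        np.testing.assert_array_equal(v, teacher_before[k])
    # every row satisfies the dynamic-weight algebra exactly
    for bd in breakdowns:
        if mode == "attention":
            w = hidden_weight(bd.loss_distill, bd.loss_ce)
            total = w * bd.loss_distill + (1 - w) * bd.loss_ce
        else:
            w = adaptive_alpha(bd.loss_ce, bd.loss_distill)
            total = (1 - w) * bd.loss_ce + w * bd.loss_distill
        assert bd.weight == pytest.approx(w, rel=1e-12)
        assert bd.loss_total == pytest.approx(total, rel=1e-6)


def test_gradients_flow_only_to_student_and_adapters(rng):
    teacher, student = _toy_pair(seed=4)
    adapters = gg.AdapterBank.for_models(teacher, student, dtype=np.float32)
    opt = Adam([], lr=1e-3)   # no-op optimizer; just inspect gradients
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    y = rng.integers(0, 6, 2)
    distill_step(teacher, student, adapters, (x, y), opt, KDConfig())
    assert all(p.grad is None for p in teacher.parameters())
    assert any(p.grad is not None and np.abs(p.grad).sum() > 0
               for p in student.parameters())
    assert any(p.grad is not None and np.abs(p.grad).sum() > 0
               for p in adapters.parameters())


def test_kdconfig_validation():
    with pytest.raises(ValueError):
        KDConfig(temperature=-1.0)
    with pytest.raises(ValueError):
        KDConfig(mode="banana")
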