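"""Fold protocol, preprocessing and the metric suite."""

import numpy as np
import pytest

import ggenet as gg
from ggenet.training import (IMAGENET_MEAN, IMAGENET_STD, compute_metrics,
                             confusion_from_predictions, fold_report,
                             make_folds, preprocess)


# ------------------------------------------------------------------- folds
def test_fold_sizes_on_balanced_100(rng):
    labels = np.repeat([0, 1], 50)
    folds = make_folds(labels, seed=0)
    assert len(folds) == 5
    for f in folds:
        assert (len(f.train_idx), len(f.val_idx), len(f.test_idx)) == (72, 8, 20)
        # stratified: both classes appear equally in each part
        for part in (f.train_idx, f.val_idx, f.test_idx):
            vals, counts = np.unique(labels[part], return_counts=True)
            assert len(vals) == 2 and counts[0] == counts[1]


def test_folds_partition_and_are_deterministic():
    labels = np.repeat(np.arange(6), 30)
    f1 = make_folds(labels, seed=9)
    f2 = make_folds(labels, seed=9)
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        allidx = np.concatenate([a.train_idx, a.val_idx, a.test_idx])
        assert len(allidx) == len(labels)
        assert len(np.unique(allidx)) == len(labels)


def test_folds_reject_tiny_class():
    with pytest.raises(ValueError, match="samples"):
        make_folds(np.array([0, 0, 0, 1, 1, 1, 1, 1]), seed=0)


# ----------------------------------------------------------- preprocessing
def test_preprocess_resizes_and_standardizes(rng):
    img = rng.integers(0, 256, (50, 37, 3), dtype=np.uint8)
    out = preprocess(img, input_size=224)
    assert out.shape == (3, 224, 224) and out.dtype == np.float32


def test_preprocess_mean_color_maps_to_zero():
    img = np.round(IMAGENET_MEAN * 255).astype(np.uint8)[None, None, :]
    img = np.broadcast_to(img, (16, 16, 3))
    out = preprocess(img, input_size=16)
    assert np.abs(out).max() < 0.02   # quantization of the mean color only


def test_preprocess_white_image_hits_known_constants():
    img = np.full((8, 8, 3), 255, dtype=np.uint8)
    out = preprocess(img, input_size=8)
    expected = (1.0 - IMAGENET_MEAN) / IMAGENET_STD
    np.testing.assert_allclose(out[:, 0, 0], expected, rtol=1e-4)
    assert out[0, 0, 0] == pytest.approx(2.2489, abs=1e-4)


def test_preprocess_rejects_non_rgb():
    with pytest.raises(ValueError, match="RGB"):
        preprocess(np.zeros((8, 8)), input_size=8)


# ----------------------------------------------------------------- metrics
def test_perfect_predictions_give_unit_metrics():
    y = np.repeat(np.arange(3), 4)
    scores = np.eye(3)[y] * 0.94 + 0.02
    cm = confusion_from_predictions(y, y, 3)
    m = compute_metrics(cm, scores, y)
    for v in (m.accuracy, m.precision, m.recall, m.f1, m.auc):
        assert v == pytest.approx(1.0)


def test_hand_computed_three_class_example():
    y_true = np.array([0, 0, 1, 1, 2, 2])
    y_pred = np.array([0, 1, 1, 1, 2, 0])
    scores = np.full((6, 3), 0.1)
    scores[np.arange(6), y_pred] = 0.8
    cm = confusion_from_predictions(y_true, y_pred, 3)
    m = compute_metrics(cm, scores, y_true)
    assert m.accuracy == pytest.approx(0.6667, abs=1e-4)
    assert m.precision == pytest.approx(0.7222, abs=1e-4)
    assert m.recall == pytest.approx(0.6667, abs=1e-4)
    assert m.f1 == pytest.approx(0.6556, abs=1e-4)


def test_weighted_recall_equals_accuracy_on_random_predictions(rng):
    """Support-weighted one-vs-rest recall is algebraically identical to
    accuracy; checked against an independent counting oracle."""
    for _ in range(200):
        k = int(rng.integers(2, 7))
        n = int(rng.integers(10, 60))
        y = rng.integers(0, k, n)
        if len(np.unique(y)) < 2:
            continue
        scores = rng.random((n, k))
        scores /= scores.sum(axis=1, keepdims=True)
        pred = scores.argmax(axis=1)
        cm = confusion_from_predictions(y, pred, k)
        m = compute_metrics(cm, scores, y)
        # independent counting oracle for accuracy and micro-F1
        acc = (pred == y).mean()
        assert abs(m.recall - acc) < 1e-12
        tp = sum((pred == c) & (y == c) for c in range(k)).sum()
        micro_f1 = tp / n   # micro precision == micro recall == accuracy
        assert m.accuracy == pytest.approx(micro_f1)
        for v in (m.accuracy, m.precision, m.recall, m.f1, m.auc):
            assert 0.0 <= v <= 1.0


def test_absent_class_excluded_with_warning():
    y = np.array([0, 0, 1, 1])   # class 2 never appears
    scores = np.full((4, 3), 0.1)
    scores[np.arange(4), y] = 0.8
    cm = confusion_from_predictions(y, y, 3)
    with pytest.warns(UserWarning, match="absent"):
        m = compute_metrics(cm, scores, y)
    assert m.accuracy == 1.0 and m.recall == 1.0


def test_confusion_matrix_total_mismatch_raises():
    with pytest.raises(ValueError, match="total"):
        compute_metrics(np.eye(2, dtype=int), np.ones((3, 2)) / 2, [0, 1, 1])


# ------------------------------------------------------ training smoke test
def test_supervised_training_learns_easy_synthetic_task():
    """Toy-width network fits an easy (low difficulty) synthetic set."""
    spec = gg.SyntheticSpec(n_per_class=60, difficulty=0.1, seed=7)
    images, labels = gg.generate_arrays(spec)
    folds = make_folds(labels, seed=7)
    mspec = gg.ModelSpec(base_width=8, attention_r=4, input_size=64)
    cfg = gg.TrainConfig(epochs=15, input_size=64, seed=7)
    net, history, best = gg.train_supervised(mspec, cfg, folds[0], (images, labels))
    assert history[-1]["train_acc"] > 0.95
    assert all(np.isfinite(h["train_loss"]) and np.isfinite(h["val_loss"])
               for h in history)
    m, cm = gg.evaluate(net, folds[0], (images, labels), cfg)
    assert cm.sum() == len(folds[0].test_idx)
    # confusion rows sum to per-class test counts
    counts = np.bincount(labels[folds[0].test_idx], minlength=6)
    np.testing.assert_array_equal(cm.sum(axis=1), counts)
    assert m.accuracy > 0.5


def test_training_is_deterministic_given_seed(small_dataset):
    images, labels = small_dataset
    folds = make_folds(labels, seed=3)
    mspec = gg.ModelSpec(base_width=2, attention_r=2, spatial_k=3, input_size=64)
    cfg = gg.TrainConfig(epochs=2, input_size=64, seed=3)
    _, h1, _ = gg.train_supervised(mspec, cfg, folds[0], (images, labels))
    _, h2, _ = gg.train_supervised(mspec, cfg, folds[0], (images, labels))
    assert h1 == h2


def test_fold_report_layout():
    ms = [gg.FoldMetrics(0.9, 0.9, 0.9, 0.9, 0.95)] * 5
    df = fold_report({"teacher": ms, "student": ms})
    assert len(df) == 12   # 5 folds + average, for each of two models
    assert np.allclose(df[df.fold == "Average"].accuracy, 0.9)
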