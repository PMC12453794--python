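"""Experimental protocol: folds, preprocessing, training, metrics.

The evaluation protocol builds five independent stratified 80/20
train/test splits (one per fold), carves a stratified 10% validation set
out of each training portion, trains with Adam (lr 1e-3, batch 16,
cross-entropy) and reports accuracy, support-weighted one-vs-rest
precision / recall / F1, and support-weighted one-vs-rest ROC AUC per
fold plus the cross-fold average. Support-weighted averaging makes the
weighted recall algebraically identical to accuracy — the property that
pins this averaging scheme. Images are bilinearly resized, scaled to
[0, 1] and standardized per channel with the ImageNet statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedShuffleSplit

from .autodiff import Adam, Tensor, no_grad, softmax_cross_entropy
from .model import GGENet, ModelSpec, build_model
from .synth import DatasetIndex

__all__ = ["FoldSplit", "TrainConfig", "FoldMetrics", "IMAGENET_MEAN",
           "IMAGENET_STD", "make_folds", "preprocess", "preprocess_batch",
           "train_supervised", "predict_proba", "compute_metrics",
           "confusion_from_predictions", "evaluate", "fold_report"]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 16
    input_size: int = 224
    seed: int = 0


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc}


# ------------------------------------------------------------------- folds
def make_folds(labels, seed: int = 0, n_folds: int = 5,
               test_frac: float = 0.2, val_frac: float = 0.1) -> list:
    """Five independent seeded stratified 80/20 splits with a 10% val carve-out."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has only {counts.min()} samples; need >= {n_folds}")
    folds = []
    for fold_id in range(1, n_folds + 1):
        outer = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                       random_state=seed * 1000 + fold_id)
        train_all, test_idx = next(outer.split(np.zeros(len(labels)), labels))
        inner = StratifiedShuffleSplit(n_splits=1, test_size=val_frac,
                                       random_state=seed * 1000 + fold_id)
        tr, va = next(inner.split(np.zeros(len(train_all)), labels[train_all]))
        folds.append(FoldSplit(fold_id, np.sort(train_all[tr]),
                               np.sort(train_all[va]), np.sort(test_idx)))
    return folds


# ------------------------------------------------------------- preprocessing
def preprocess(image, input_size: int = 224) -> np.ndarray:
    """One RGB image (path, PIL image or HWC array) -> (3, S, S) float32."""
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        with Image.open(image) as im:
            image = np.asarray(im.convert("RGB"))
    elif isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {image.shape}")
    if image.shape[0] != input_size or image.shape[1] != input_size:
        pil = Image.fromarray(image.astype(np.uint8))
        image = np.asarray(pil.resize((input_size, input_size), Image.BILINEAR))
    x = image.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN.astype(np.float32)) / IMAGENET_STD.astype(np.float32)
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def preprocess_batch(images: np.ndarray, input_size: int) -> np.ndarray:
    """Vectorized preprocess of a (N, H, W, 3) uint8 stack -> (N, 3, S, S)."""
    images = np.asarray(images)
    if images.shape[1] == input_size and images.shape[2] == input_size:
        x = images.astype(np.float32) / 255.0
        x = (x - IMAGENET_MEAN.astype(np.float32)) / IMAGENET_STD.astype(np.float32)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    return np.stack([preprocess(im, input_size) for im in images])


def _resolve_images(data) -> tuple:
    """(images (N,H,W,3) uint8, labels) from arrays or a DatasetIndex."""
    if isinstance(data, DatasetIndex):
        if data.images is not None:
            return data.images, data.labels
        imgs = np.stack([np.asarray(Image.open(p).convert("RGB"))
                         for p in data.paths])
        return imgs, data.labels
    images, labels = data
    return np.asarray(images), np.asarray(labels)


# ---------------------------------------------------------------- training
def train_supervised(spec: ModelSpec, cfg: TrainConfig, split: FoldSplit,
                     data, verbose: bool = False) -> tuple:
    """Train one network on a fold; returns (net, history, best_state).

    history is a list of per-epoch dicts (train loss/acc, val loss/acc);
    best_state is the state dict at the best validation accuracy.
    """
    images, labels = _resolve_images(data)
    if len(split.train_idx) == 0 or len(split.val_idx) == 0:
        raise ValueError("empty train or validation split")
    x_all = preprocess_batch(images, cfg.input_size)
    net = build_model(spec, seed=cfg.seed, dtype=np.float32)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(split.train_idx)
        losses, correct = [], 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = net(Tensor(x_all[idx]))
            loss = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        val_loss, val_acc = _eval_loss_acc(net, x_all, labels, split.val_idx,
                                           cfg.batch_size)
        row = {"epoch": epoch + 1,
               "train_loss": float(np.mean(losses)),
               "train_acc": correct / len(order),
               "val_loss": val_loss, "val_acc": val_acc}
        history.append(row)
        if val_acc > best_acc:
            best_acc, best_state = val_acc, net.state_dict()
        if verbose:
            print(f"epoch {row['epoch']:3d}  train_loss {row['train_loss']:.4f}  "
                  f"train_acc {row['train_acc']:.4f}  val_acc {val_acc:.4f}")
    return net, history, best_state


def _eval_loss_acc(net, x_all, labels, idx, batch_size) -> tuple:
    losses, correct = [], 0
    with no_grad():
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo:lo + batch_size]
            logits = net(Tensor(x_all[sel]))
            losses.append(softmax_cross_entropy(logits, labels[sel]).item())
            correct += int((logits.data.argmax(axis=1) == labels[sel]).sum())
    return float(np.mean(losses)), correct / len(idx)


def predict_proba(net: GGENet, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Softmax class probabilities, batched, no gradient tracking."""
    probs = []
    with no_grad():
        for lo in range(0, len(x), batch_size):
            z = net(Tensor(x[lo:lo + batch_size])).data
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(probs)


# ----------------------------------------------------------------- metrics
def confusion_from_predictions(y_true, y_pred, n_classes: int) -> np.ndarray:
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def compute_metrics(cm: np.ndarray, scores: np.ndarray, labels) -> FoldMetrics:
    """Accuracy plus support-weighted one-vs-rest precision/recall/F1/AUC.

    `cm` is the K x K confusion matrix (rows true, columns predicted),
    `scores` the per-sample class-probability matrix, `labels` the true
    labels for the scored samples. Classes absent from `labels` are
    excluded from the weighted averages with a warning (their weight is
    zero under support weighting; AUC renormalizes over present classes).
    """
    cm = np.asarray(cm)
    labels = np.asarray(labels)
    if cm.sum() != len(labels):
        raise ValueError("confusion matrix total does not match label count")
    accuracy = float(np.trace(cm) / cm.sum())
    y_pred = _predictions_from_cm_order(scores)
    present = np.unique(labels)
    if len(present) < cm.shape[0]:
        warnings.warn("some classes absent from the evaluated labels; "
                      "weighted averages cover present classes only", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            labels, y_pred, labels=present, average="weighted", zero_division=0)
    if len(present) == 1:
        auc = float("nan")
    elif len(present) == 2:
        auc = float(roc_auc_score(labels, scores[:, present[1]]))
    elif len(present) < scores.shape[1]:
        sub = scores[:, present]
        sub = sub / sub.sum(axis=1, keepdims=True)
        auc = float(roc_auc_score(labels, sub, multi_class="ovr",
                                  average="weighted", labels=present))
    else:
        auc = float(roc_auc_score(labels, scores, multi_class="ovr",
                                  average="weighted"))
    return FoldMetrics(accuracy, float(precision), float(recall), float(f1), auc)


def _predictions_from_cm_order(scores: np.ndarray) -> np.ndarray:
    return np.asarray(scores).argmax(axis=1)


def evaluate(net: GGENet, split: FoldSplit, data, cfg: TrainConfig) -> tuple:
    """Deterministic test-set metrics for one fold: (FoldMetrics, cm)."""
    images, labels = _resolve_images(data)
    if len(split.test_idx) == 0:
        raise ValueError("empty test split")
    n_classes = net.spec.n_classes
    if labels.max() >= n_classes:
        raise ValueError("dataset has more classes than the checkpoint")
    x = preprocess_batch(images[split.test_idx], cfg.input_size)
    y = labels[split.test_idx]
    scores = predict_proba(net, x, cfg.batch_size)
    y_pred = scores.argmax(axis=1)
    cm = confusion_from_predictions(y, y_pred, n_classes)
    return compute_metrics(cm, scores, y), cm


def fold_report(per_model: dict):
    """Tidy table of per-fold metrics plus an Average row per model."""
    import pandas as pd

    rows = []
    for model, metrics_list in per_model.items():
        for fold_id, m in enumerate(metrics_list, start=1):
            rows.append({"fold": str(fold_id), "model": model, **m.as_dict()})
        avg = {k: float(np.mean([m.as_dict()[k] for m in metrics_list]))
               for k in ("accuracy", "precision", "recall", "f1", "auc")}
        rows.append({"fold": "Average", "model": model, **avg})
    return pd.DataFrame(rows)
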