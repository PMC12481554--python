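"""Concentration classifier and its full evaluation suite.

Training follows the fixed recipe used across all architecture
comparisons: batch size 32, Adam (learning rate 1e-4), cross-entropy
loss, 100 epochs, 128×128×3 inputs — all configurable.  The default
architecture is ``tiny_cnn``, a three-block convolutional network with
global average pooling, small enough that toy-scale runs finish in
seconds on one CPU; the registry also lists the larger mobile
architectures by name for completeness, but they are not provided in
this build.

Evaluation: confusion matrices (rows = true class, columns = predicted),
one-vs-rest sensitivity / specificity / PPV / NPV per class, overall
accuracy, one-vs-rest ROC curves with trapezoidal AUC, and t-SNE
embeddings for visual inspection.  Metric ratios with zero denominators
are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .nn import Adam, Conv2d, Linear, Module, Tensor, cross_entropy, no_grad, softmax


class ClassifyError(ValueError):
    pass


class ModelUnavailableError(ClassifyError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    model_name: str = "tiny_cnn"
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 100
    input_size: int = 128
    seed: int = 0


#: classifier profile for the 16×16 toy experiments
TOY_TRAIN = TrainConfig(input_size=16, epochs=8, learning_rate=3e-3)


class TinyCNN(Module):
    """Three conv blocks (stride-2 pooling via stride), GAP, linear head."""

    def __init__(self, n_classes: int, rng: np.random.Generator):
        self.c1 = Conv2d(3, 8, 3, rng, stride=2)
        self.c2 = Conv2d(8, 16, 3, rng, stride=2)
        self.c3 = Conv2d(16, 32, 3, rng)
        self.head = Linear(32, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        pooled = h.mean(axis=(2, 3))
        return self.head(pooled)


def _unavailable(name):
    def build(n_classes, rng):
        raise ModelUnavailableError(
            f"architecture {name!r} is registered but not provided in this "
            f"build; use 'tiny_cnn'")
    return build


MODEL_REGISTRY = {
    "tiny_cnn": lambda n_classes, rng: TinyCNN(n_classes, rng),
    "resnet50": _unavailable("resnet50"),
    "mobilenet_v2": _unavailable("mobilenet_v2"),
    "efficientnet_b0": _unavailable("efficientnet_b0"),
}


@dataclass
class Classifier:
    """Trained model plus its label vocabulary (sorted class names)."""

    module: Module
    classes: list[str]
    cfg: TrainConfig

    def encode(self, labels) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[lab] for lab in labels])


def train_classifier(train: LabeledDataset, val: LabeledDataset,
                     cfg: TrainConfig = TrainConfig(),
                     ) -> tuple[Classifier, dict]:
    """Minimize cross-entropy with Adam; keep the best-val-accuracy weights.

    Returns the classifier (loaded with the best checkpoint) and a history
    dict with per-epoch train/val loss and accuracy (``epochs`` entries).
    """
    if len(train) == 0 or len(val) == 0:
        raise ClassifyError("empty split")
    train_labels = set(train.labels)
    if train_labels != set(val.labels):
        raise ClassifyError(
            f"label sets differ: train {sorted(train_labels)} vs "
            f"val {sorted(set(val.labels))}")
    if cfg.model_name not in MODEL_REGISTRY:
        raise ClassifyError(f"unknown model {cfg.model_name!r}")
    classes = sorted(train_labels)
    rng = np.random.default_rng(cfg.seed)
    module = MODEL_REGISTRY[cfg.model_name](len(classes), rng)
    clf = Classifier(module=module, classes=classes, cfg=cfg)

    x_train = train.images()
    if x_train.shape[2] != cfg.input_size or x_train.shape[3] != cfg.input_size:
        raise ClassifyError(
            f"images {x_train.shape[2:]} do not match input_size "
            f"{cfg.input_size}")
    y_train = clf.encode(train.labels)
    x_val = val.images()
    y_val = clf.encode(val.labels)

    opt = Adam(module.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_state = -1.0, None
    n = len(train)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = module(Tensor(x_train[idx]))
            loss = cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        tr_loss, tr_acc = _evaluate(module, x_train, y_train)
        va_loss, va_acc = _evaluate(module, x_val, y_val)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_acc > best_acc:
            best_acc = va_acc
            best_state = module.state()
    if best_state is not None:
        module.load_state(best_state)
    return clf, history


def _evaluate(module: Module, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    with no_grad():
        for start in range(0, len(x), batch):
            logits = module(Tensor(x[start:start + batch]))
            losses.append(float(
                cross_entropy(logits, y[start:start + batch]).data)
                * len(logits.data))
            correct += int((logits.data.argmax(axis=1)
                            == y[start:start + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict_proba(clf: Classifier, images) -> np.ndarray:
    """Per-class probabilities; each row is non-negative and sums to 1."""
    x = images.images() if isinstance(images, LabeledDataset) else np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    out = []
    with no_grad():
        for start in range(0, len(x), 256):
            logits = clf.module(Tensor(x[start:start + 256]))
            out.append(softmax(logits, axis=1).data)
    return np.concatenate(out)


def predict(clf: Classifier, images) -> list[str]:
    proba = predict_proba(clf, images)
    return [clf.classes[i] for i in proba.argmax(axis=1)]


# -- metrics -------------------------------------------------------------------

def confusion(preds, labels, n_classes: int) -> np.ndarray:
    """K×K integer counts; rows are true classes, columns predictions."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ClassifyError("preds and labels must have equal length")
    from sklearn.metrics import confusion_matrix

    if len(labels) == 0:
        return np.zeros((n_classes, n_classes), dtype=np.int64)
    return confusion_matrix(labels, preds,
                            labels=np.arange(n_classes)).astype(np.int64)


def class_metrics(cm: np.ndarray, class_names=None) -> dict:
    """One-vs-rest SEN/SPE/PPV/NPV per class plus overall accuracy.

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN);
    a zero denominator yields NaN.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = cm.sum()
    names = class_names if class_names is not None else list(range(k))
    per_class = {}
    for i in range(k):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[names[i]] = {
            "SEN": _ratio(tp, tp + fn),
            "SPE": _ratio(tn, tn + fp),
            "PPV": _ratio(tp, tp + fp),
            "NPV": _ratio(tn, tn + fn),
        }
    accuracy = _ratio(np.trace(cm), total)
    return {"accuracy": accuracy, "per_class": per_class}


def _ratio(num, den) -> float:
    return float(num) / float(den) if den > 0 else float("nan")


def roc_curves(proba: np.ndarray, labels) -> dict:
    """One-vs-rest ROC per class (threshold sweep) with trapezoidal AUC.

    Returns {class index: {"fpr", "tpr", "thresholds", "auc", "undefined"}};
    a class absent (or alone) in ``labels`` gets ``undefined=True`` and a
    NaN AUC.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    proba = np.asarray(proba)
    labels = np.asarray(labels)
    out = {}
    for k in range(proba.shape[1]):
        y = (labels == k).astype(int)
        if y.min() == y.max():
            out[k] = {"fpr": None, "tpr": None, "thresholds": None,
                      "auc": float("nan"), "undefined": True}
            continue
        fpr, tpr, thr = roc_curve(y, proba[:, k])
        out[k] = {"fpr": fpr, "tpr": tpr, "thresholds": thr,
                  "auc": float(sk_auc(fpr, tpr)), "undefined": False}
    return out


def tsne_embed(features: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding (export-only diagnostic), seed-reproducible."""
    features = np.asarray(features)
    if len(features) < 3 * perplexity:
        raise ClassifyError(
            f"need at least {int(3 * perplexity)} samples for perplexity "
            f"{perplexity}, got {len(features)}")
    from sklearn.manifold import TSNE

    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(features)
    return np.asarray(emb)


def features(clf: Classifier, images) -> np.ndarray:
    """Penultimate-layer (global-average-pooled) features for t-SNE."""
    x = images.images() if isinstance(images, LabeledDataset) else np.asarray(images)
    m = clf.module
    out = []
    with no_grad():
        for start in range(0, len(x), 256):
            h = m.c1(Tensor(x[start:start + 256])).relu()
            h = m.c2(h).relu()
            h = m.c3(h).relu()
            out.append(h.mean(axis=(2, 3)).data)
    return np.concatenate(out)
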