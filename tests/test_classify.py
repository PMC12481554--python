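"""Classifier training and the evaluation metric suite."""

import numpy as np
import pytest

from stripgan import stripsim
from stripgan.classify import (
    Classifier,
    ClassifyError,
    ModelUnavailableError,
    TinyCNN,
    TrainConfig,
    TOY_TRAIN,
    class_metrics,
    confusion,
    features,
    predict_proba,
    roc_curves,
    train_classifier,
    tsne_embed,
)
from stripgan.datasets import holdout_split


def fresh_classifier(rng, n_classes=3):
    return Classifier(module=TinyCNN(n_classes, rng),
                      classes=["blank", "low", "high"][:n_classes],
                      cfg=TOY_TRAIN)


class TestPredictProba:
    def test_rows_normalized_nonnegative(self, rng):
        clf = fresh_classifier(rng)
        x = rng.random((10, 3, 16, 16))
        proba = predict_proba(clf, x)
        assert proba.shape == (10, 3)
        assert (proba >= 0).all()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_identical_rows(self, rng):
        clf = fresh_classifier(rng)
        x = rng.random((1, 3, 16, 16))
        proba = predict_proba(clf, np.concatenate([x, x]))
        assert np.array_equal(proba[0], proba[1])

    def test_single_image(self, rng):
        clf = fresh_classifier(rng)
        assert predict_proba(clf, rng.random((3, 16, 16))).shape == (1, 3)


class TestTraining:
    def test_errors(self, toy_dataset):
        train, val = holdout_split(toy_dataset, 0.8, seed=0)
        bad_val = val.subset([i for i, r in enumerate(val)
                              if r.label != "high"])
        with pytest.raises(ClassifyError):
            train_classifier(train, bad_val, TOY_TRAIN)
        with pytest.raises(ModelUnavailableError):
            train_classifier(train, val,
                             TrainConfig(model_name="resnet50", input_size=16,
                                         epochs=1))

    def test_history_length_and_seed_determinism(self, toy_dataset):
        train, val = holdout_split(toy_dataset, 0.8, seed=0)
        cfg = TrainConfig(input_size=16, epochs=2, learning_rate=1e-3, seed=5)
        clf_a, hist_a = train_classifier(train, val, cfg)
        clf_b, hist_b = train_classifier(train, val, cfg)
        assert len(hist_a["val_acc"]) == 2
        assert hist_a == hist_b
        for pa, pb in zip(clf_a.module.parameters(),
                          clf_b.module.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_toy_task_learnable(self):
        """The band-contrast toy task reaches >0.9 validation accuracy within
        a few epochs for a majority of seeds."""
        wins = 0
        for seed in (21, 22, 23):
            ds = stripsim.sample_dataset(125, seed=seed,
                                         profile=stripsim.TOY_PROFILE,
                                         height=16, width=16)
            train, val = holdout_split(ds, 0.8, seed=seed)
            cfg = TrainConfig(input_size=16, epochs=8, learning_rate=3e-3,
                              seed=seed)
            _, hist = train_classifier(train, val, cfg)
            wins += max(hist["val_acc"]) > 0.9
        assert wins >= 2


def thirty_strip_scenario():
    """10 strips per class; two low-concentration strips called high."""
    classes = ["blank", "high", "low"]  # alphabetical encoding order
    y_true = [0] * 10 + [1] * 10 + [2] * 10
    y_pred = list(y_true)
    y_pred[20] = 1
    y_pred[21] = 1
    return np.array(y_pred), np.array(y_true), classes


class TestConfusion:
    def test_thirty_strip_counts(self):
        y_pred, y_true, _ = thirty_strip_scenario()
        cm = confusion(y_pred, y_true, 3)
        assert cm[2, 1] == 2                       # low called high
        off_diag = cm - np.diag(np.diag(cm))
        assert off_diag.sum() == 2
        assert cm.sum() == 30

    def test_perfect_and_empty(self):
        assert np.array_equal(confusion([0, 1, 2], [0, 1, 2], 3), np.eye(3))
        assert confusion([], [], 3).sum() == 0

    def test_length_mismatch(self):
        with pytest.raises(ClassifyError):
            confusion([0, 1], [0], 2)


class TestClassMetrics:
    def test_thirty_strip_worked_example(self):
        y_pred, y_true, classes = thirty_strip_scenario()
        cm = confusion(y_pred, y_true, 3)
        m = class_metrics(cm, class_names=classes)
        assert m["accuracy"] == pytest.approx(28 / 30)
        assert round(100 * m["accuracy"], 2) == 93.33
        assert m["per_class"]["low"]["SEN"] == pytest.approx(8 / 10)
        assert m["per_class"]["high"]["SPE"] == pytest.approx(18 / 20)
        assert m["per_class"]["blank"]["SEN"] == 1.0
        assert m["per_class"]["blank"]["SPE"] == 1.0

    def test_diagonal_matrix_all_ones(self):
        m = class_metrics(np.diag([5, 3, 2]))
        assert m["accuracy"] == 1.0
        for stats in m["per_class"].values():
            assert stats["SEN"] == 1.0 and stats["SPE"] == 1.0

    def test_zero_denominator_is_nan_not_zero(self):
        cm = np.array([[5, 0], [0, 0]])  # class 1 never occurs
        m = class_metrics(cm)
        assert np.isnan(m["per_class"][1]["SEN"])
        assert np.isnan(m["per_class"][1]["PPV"])

    def test_matches_counting_oracle(self, rng):
        """Exact agreement with per-sample TP/TN/FP/FN counting on 1,000
        random prediction/label vectors."""
        y_true = rng.integers(0, 3, size=1000)
        y_pred = rng.integers(0, 3, size=1000)
        cm = confusion(y_pred, y_true, 3)
        m = class_metrics(cm)
        assert m["accuracy"] == np.mean(y_pred == y_true)
        for k in range(3):
            tp = int(np.sum((y_true == k) & (y_pred == k)))
            fn = int(np.sum((y_true == k) & (y_pred != k)))
            fp = int(np.sum((y_true != k) & (y_pred == k)))
            tn = int(np.sum((y_true != k) & (y_pred != k)))
            assert m["per_class"][k]["SEN"] == tp / (tp + fn)
            assert m["per_class"][k]["SPE"] == tn / (tn + fp)
            assert m["per_class"][k]["PPV"] == tp / (tp + fp)
            assert m["per_class"][k]["NPV"] == tn / (tn + fn)


class TestROC:
    def test_perfect_separation(self):
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        labels = np.array([0, 0, 1, 1])
        roc = roc_curves(proba, labels)
        assert roc[0]["auc"] == 1.0 and roc[1]["auc"] == 1.0

    def test_matches_pairwise_concordance_oracle(self, rng):
        """AUC equals the concordant-pair fraction (ties count half)."""
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        proba = np.column_stack([1 - scores, scores])
        auc = roc_curves(proba, labels)[1]["auc"]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-9)

    def test_permuted_labels_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.permutation([0] * 1000 + [1] * 1000)
        proba = np.column_stack([1 - scores, scores])
        assert roc_curves(proba, labels)[1]["auc"] == pytest.approx(0.5,
                                                                    abs=0.05)

    def test_single_class_flagged_undefined(self):
        proba = np.array([[0.6, 0.4], [0.3, 0.7]])
        roc = roc_curves(proba, np.array([1, 1]))
        assert roc[0]["undefined"] and roc[1]["undefined"]
        assert np.isnan(roc[0]["auc"])


class TestTSNE:
    def test_shape_and_determinism(self, rng):
        feats = rng.normal(size=(60, 8))
        a = tsne_embed(feats, perplexity=10, seed=3)
        b = tsne_embed(feats, perplexity=10, seed=3)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_too_few_samples(self, rng):
        with pytest.raises(ClassifyError):
            tsne_embed(rng.normal(size=(20, 4)), perplexity=10)

    def test_separated_blobs_stay_separated(self):
        from sklearn.metrics import silhouette_score

        wins = 0
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 0.3, size=(50, 6))
            b = rng.normal(5, 0.3, size=(50, 6))
            feats = np.vstack([a, b])
            labels = np.array([0] * 50 + [1] * 50)
            emb = tsne_embed(feats, perplexity=15, seed=seed)
            wins += silhouette_score(emb, labels) > 0.5
        assert wins >= 2


def test_feature_extractor_shape(rng, toy_dataset):
    clf = fresh_classifier(rng)
    feats = features(clf, toy_dataset[:8])
    assert feats.shape == (8, 32)
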