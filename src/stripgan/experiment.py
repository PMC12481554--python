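"""Toy-scale orchestration of the data-composition experiment grid.

One run executes the full pipeline — simulate real strips → train one
Wasserstein GAN per class → generate synthetic images → QC-filter →
assemble a training composition (real-only, 50/50 mixed, or absolute
counts such as 10%/90% and 1%/99% real/synthetic) → hold-out split →
train the classifier → evaluate on an independently simulated test
fixture — for every (composition × dataset size) cell of the declared
grid, and emits one consolidated row per cell plus per-cell reports.

Everything is seeded from the spec: the simulator, each per-class GAN,
generation, QC order, mixing subsamples, the split and the classifier.
Trained GANs are cached on disk content-addressed by their stage
parameters and seed, so reruns of the same spec skip the expensive stage.

Scale defaults are deliberately small (16×16 strips, hundreds of images,
a few hundred GAN updates, ≤10 classifier epochs); the full-size numbers
from the lab workflow are configuration values, not constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, datasets, gan, preprocess, qc, stripsim
from .datasets import CLASSES, LabeledDataset


@dataclass(frozen=True)
class Composition:
    name: str
    mode: str = "real_only"          # real_only | ratio | counts
    ratio: float = 0.5               # real fraction (ratio mode)
    real_frac: float = 0.1           # real fraction (counts mode)


DEFAULT_COMPOSITIONS = (
    Composition("real_only", "real_only"),
    Composition("mixed_50_50", "ratio", ratio=0.5),
)


@dataclass(frozen=True)
class ExperimentSpec:
    seed: int = 0
    image_size: int = 16
    noise_sd: float = 0.02
    n_real_per_class: int = 100
    n_test_per_class: int = 40
    n_synthetic_per_class: int = 150
    sizes: tuple[int, ...] = (150, 300)
    compositions: tuple[Composition, ...] = DEFAULT_COMPOSITIONS
    gan_steps: int = 200
    gan_base_channels: int = 8
    gan_noise_dim: int = 32
    gan_learning_rate: float = 2e-4
    attention_enabled: bool = True
    clf_epochs: int = 8
    clf_learning_rate: float = 3e-3
    ssim_max: float = 0.95
    hamming_min: int = 4

    @staticmethod
    def from_yaml(path) -> "ExperimentSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        comps = raw.pop("compositions", None)
        spec = ExperimentSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.items()})
        if comps is not None:
            spec = dataclasses.replace(
                spec, compositions=tuple(Composition(**c) for c in comps))
        return spec


def _profile(spec: ExperimentSpec) -> stripsim.SimProfile:
    return dataclasses.replace(stripsim.TOY_PROFILE, noise_sd=spec.noise_sd)


def _gan_config(spec: ExperimentSpec, seed: int) -> gan.GANConfig:
    return gan.GANConfig(image_size=spec.image_size,
                         base_channels=spec.gan_base_channels,
                         noise_dim=spec.gan_noise_dim,
                         attention_enabled=spec.attention_enabled,
                         learning_rate=spec.gan_learning_rate,
                         steps=spec.gan_steps, seed=seed)


def _stage_key(stage: str, **params) -> str:
    blob = json.dumps({"stage": stage, **params}, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def simulate_pools(spec: ExperimentSpec
                   ) -> tuple[LabeledDataset, LabeledDataset]:
    """Real training pool and an independent test fixture (fresh seed)."""
    profile = _profile(spec)
    pool = stripsim.sample_dataset(spec.n_real_per_class, seed=spec.seed,
                                   profile=profile, height=spec.image_size,
                                   width=spec.image_size)
    test = stripsim.sample_dataset(spec.n_test_per_class, seed=spec.seed + 1000,
                                   profile=profile, height=spec.image_size,
                                   width=spec.image_size)
    return pool, test


def train_synthetic_pool(spec: ExperimentSpec, real_pool: LabeledDataset,
                         cache_dir: Path | None = None) -> LabeledDataset:
    """One GAN per class → generate → QC filter; returns the accepted pool."""
    thresholds = qc.QCThresholds(ssim_max=spec.ssim_max,
                                 hamming_min=spec.hamming_min)
    parts = []
    for ci, class_label in enumerate(CLASSES):
        gan_seed = spec.seed + 100 + ci
        cfg = _gan_config(spec, gan_seed)
        key = _stage_key("gan", cls=class_label,
                         cfg=dataclasses.asdict(cfg), sim_seed=spec.seed,
                         n_real=spec.n_real_per_class,
                         noise_sd=spec.noise_sd)
        generator = None
        if cache_dir is not None:
            ckpt = Path(cache_dir) / f"gan-{key}.npz"
            if ckpt.exists():
                generator, _ = gan.load_checkpoint(ckpt.with_suffix(""),
                                                   kind="generator")
        if generator is None:
            class_ds = LabeledDataset(
                r for r in real_pool if r.label == class_label)
            generator, _, _ = gan.train(class_ds, cfg)
            if cache_dir is not None:
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                gan.save_checkpoint(generator, cfg,
                                    Path(cache_dir) / f"gan-{key}",
                                    step=cfg.steps or 0)
        # oversample so the pool survives QC at full size
        raw = gan.generate(generator, int(spec.n_synthetic_per_class * 1.5),
                           seed=gan_seed + 5000, class_label=class_label)
        accepted, _ = qc.filter_generated(raw, thresholds)
        parts.append(accepted[:spec.n_synthetic_per_class])
    pool = parts[0]
    for p in parts[1:]:
        pool = pool.concat(p)
    return pool


def _compose(comp: Composition, n: int, real_pool: LabeledDataset,
             synth_pool: LabeledDataset, seed: int) -> LabeledDataset:
    rng = np.random.default_rng(seed)
    if comp.mode == "real_only":
        return datasets._stratified_take(real_pool, n, rng)
    if comp.mode == "ratio":
        n_real = int(round(n * comp.ratio))
        return datasets.mix_counts(real_pool, synth_pool,
                                   n_real, n - n_real, seed=seed)
    if comp.mode == "counts":
        n_real = max(1, int(round(n * comp.real_frac)))
        return datasets.mix_counts(real_pool, synth_pool,
                                   n_real, n - n_real, seed=seed)
    raise ValueError(f"unknown composition mode {comp.mode!r}")


def evaluate_classifier(clf: classify.Classifier,
                        test: LabeledDataset) -> dict:
    """Accuracy plus per-class SEN/SPE on a labeled test set."""
    y_true = clf.encode(test.labels)
    proba = classify.predict_proba(clf, test)
    y_pred = proba.argmax(axis=1)
    cm = classify.confusion(y_pred, y_true, len(clf.classes))
    metrics = classify.class_metrics(cm, class_names=clf.classes)
    row = {"accuracy": metrics["accuracy"]}
    for name in clf.classes:
        row[f"sen_{name}"] = metrics["per_class"][name]["SEN"]
        row[f"spe_{name}"] = metrics["per_class"][name]["SPE"]
    return row


def run_experiment(spec: ExperimentSpec,
                   out_dir: str | Path | None = None
                   ) -> pd.DataFrame:
    """Execute the composition × size grid; one consolidated row per cell.

    A failing cell is recorded with its error message and does not abort
    the remaining cells.
    """
    out = Path(out_dir) if out_dir is not None else None
    cache_dir = out / "cache" if out is not None else None
    real_pool, test = simulate_pools(spec)
    synth_pool = train_synthetic_pool(spec, real_pool, cache_dir=cache_dir)
    clf_cfg = classify.TrainConfig(input_size=spec.image_size,
                                   epochs=spec.clf_epochs,
                                   learning_rate=spec.clf_learning_rate,
                                   seed=spec.seed + 77)
    rows = []
    for comp in spec.compositions:
        for n in spec.sizes:
            row = {"composition": comp.name, "n": n}
            try:
                train_ds = _compose(comp, n, real_pool, synth_pool,
                                    seed=spec.seed + 7)
                tr, va = datasets.holdout_split(train_ds, 0.8,
                                                seed=spec.seed + 8)
                clf, _ = classify.train_classifier(tr, va, clf_cfg)
                row.update(evaluate_classifier(clf, test))
                row["error"] = ""
            except Exception as exc:  # keep the grid going
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    report = pd.DataFrame(rows)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "results.csv", index=False,
                      float_format="%.6f")
        (out / "spec.json").write_text(json.dumps(
            dataclasses.asdict(spec), indent=2, default=list))
    return report


def augmentation_only_baseline(spec: ExperimentSpec,
                               flip_axes: tuple[str, ...] = ("horizontal",),
                               out_dir: str | Path | None = None
                               ) -> pd.DataFrame:
    """Geometric-augmentation-only comparator (no GAN).

    The training pool is the real pool plus mirrored copies (the dataset
    doubles per flip axis requested); evaluation uses the same test
    fixture and row schema as :func:`run_experiment`.
    """
    real_pool, test = simulate_pools(spec)
    pool = real_pool
    for axis in flip_axes:
        flipped = [datasets.Record(image=preprocess.flip(r.image, axis),
                                   label=r.label, provenance=r.provenance,
                                   meta={**r.meta, "flip": axis})
                   for r in pool]
        pool = LabeledDataset(list(pool.records) + flipped)
    clf_cfg = classify.TrainConfig(input_size=spec.image_size,
                                   epochs=spec.clf_epochs,
                                   learning_rate=spec.clf_learning_rate,
                                   seed=spec.seed + 77)
    tr, va = datasets.holdout_split(pool, 0.8, seed=spec.seed + 8)
    clf, _ = classify.train_classifier(tr, va, clf_cfg)
    row = {"composition": f"augment_only_{'_'.join(flip_axes)}",
           "n": len(pool)}
    row.update(evaluate_classifier(clf, test))
    row["error"] = ""
    report = pd.DataFrame([row])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "augmentation_baseline.csv", index=False,
                      float_format="%.6f")
    return report
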