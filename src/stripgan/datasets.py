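"""Labeled image collections: real/synthetic mixing, label schemes, splits.

The universal container is :class:`LabeledDataset`, an ordered list of
records each holding a 3×H×W float image in [0, 1], a class label, a
provenance tag (``real`` or ``synthetic``) and free-form metadata
(concentration in μg/mL, render seed, rotation angle, ...).

Label schemes
-------------
``three_class``  blank / low / high — the default grouping: 0 μg/mL is
                 blank, {0.25, 0.5} low, {0.75, 1.0} high.
``binary``       negative (blank) / positive (any analyte present).
``five_level``   one label per concentration level.
"""

from __future__ import annotations

import csv
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from PIL import Image

CLASSES: tuple[str, ...] = ("blank", "low", "high")
CONCENTRATIONS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
#: concentration (μg/mL) → three-class label
CONC_TO_CLASS: dict[float, str] = {
    0.0: "blank", 0.25: "low", 0.5: "low", 0.75: "high", 1.0: "high",
}
PROVENANCES = ("real", "synthetic")
LABEL_SCHEMES = ("three_class", "binary", "five_level")


class DatasetError(ValueError):
    """Raised for malformed datasets or infeasible mixing requests."""


@dataclass
class Record:
    image: np.ndarray
    label: str
    provenance: str
    meta: dict = field(default_factory=dict)
    ref: str = field(default_factory=lambda: uuid.uuid4().hex)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise DatasetError(f"provenance must be one of {PROVENANCES}, "
                               f"got {self.provenance!r}")


class LabeledDataset:
    """Ordered collection of labeled, provenance-tagged images."""

    def __init__(self, records: Iterable[Record]):
        self.records: list[Record] = list(records)
        refs = [r.ref for r in self.records]
        if len(set(refs)) != len(refs):
            raise DatasetError("duplicate image refs in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return LabeledDataset(self.records[idx])
        return self.records[idx]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.provenance] = counts.get(r.provenance, 0) + 1
        return counts

    def images(self) -> np.ndarray:
        """Stack all images into an (N, 3, H, W) array."""
        return np.stack([r.image for r in self.records])

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset(self.records[i] for i in indices)

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(list(self.records) + list(other.records))

    # -- persistence ----------------------------------------------------------
    def save(self, root: str | Path) -> Path:
        """Write ``<root>/<label>/<ref>.png`` plus a CSV manifest.

        Returns the manifest path.
        """
        root = Path(root)
        rows = []
        for r in self.records:
            cdir = root / r.label
            cdir.mkdir(parents=True, exist_ok=True)
            path = cdir / f"{r.ref}.png"
            arr = np.clip(r.image, 0.0, 1.0)
            Image.fromarray(
                (np.moveaxis(arr, 0, 2) * 255).round().astype(np.uint8)
            ).save(path)
            rows.append({
                "path": str(path.relative_to(root)),
                "class": r.label,
                "concentration": r.meta.get("concentration", ""),
                "seed": r.meta.get("seed", ""),
                "provenance": r.provenance,
                "rotation_deg": r.meta.get("rotation_deg", ""),
            })
        manifest = root / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        return manifest

    @staticmethod
    def load(manifest: str | Path) -> "LabeledDataset":
        manifest = Path(manifest)
        root = manifest.parent
        records = []
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                arr = np.asarray(Image.open(root / row["path"]),
                                 dtype=np.float64) / 255.0
                meta = {}
                if row.get("concentration"):
                    meta["concentration"] = float(row["concentration"])
                if row.get("seed"):
                    meta["seed"] = int(row["seed"])
                if row.get("rotation_deg"):
                    meta["rotation_deg"] = float(row["rotation_deg"])
                records.append(Record(
                    image=np.moveaxis(arr, 2, 0),
                    label=row["class"],
                    provenance=row["provenance"],
                    meta=meta,
                    ref=Path(row["path"]).stem,
                ))
        return LabeledDataset(records)


# -- stratified sampling helpers -----------------------------------------------

def _stratified_take(ds: LabeledDataset, n: int,
                     rng: np.random.Generator) -> LabeledDataset:
    """Seeded subsample of ``n`` records, balanced across classes.

    Classes receive ``n // k`` records each plus one extra for the first
    ``n % k`` classes in sorted label order; raises if any class runs short.
    """
    if n > len(ds):
        raise DatasetError(f"cannot take {n} records from a pool of {len(ds)}")
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(ds.records):
        by_class.setdefault(r.label, []).append(i)
    labels = sorted(by_class)
    k = len(labels)
    base, extra = divmod(n, k)
    chosen: list[int] = []
    for j, lab in enumerate(labels):
        want = base + (1 if j < extra else 0)
        pool = by_class[lab]
        if want > len(pool):
            raise DatasetError(
                f"class {lab!r} has only {len(pool)} records, need {want}")
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    chosen.sort()
    return ds.subset(chosen)


# -- mixing --------------------------------------------------------------------

def mix(real: LabeledDataset, synthetic: LabeledDataset,
        ratio: float = 0.5, seed: int = 0) -> LabeledDataset:
    """Combine real and synthetic pools at a real-fraction ``ratio``.

    If the pool sizes already satisfy the ratio the pools are concatenated
    unchanged; otherwise the over-supplied pool is subsampled (seeded,
    class-balanced) so that ``|real| / total == ratio`` up to rounding.
    """
    if not len(real) or not len(synthetic):
        raise DatasetError("both pools must be nonempty")
    if not 0.0 < ratio < 1.0:
        raise DatasetError("ratio must be in (0, 1)")
    classes = set(real.labels) | set(synthetic.labels)
    for name, pool in (("real", real), ("synthetic", synthetic)):
        missing = classes - set(pool.labels)
        if missing:
            raise DatasetError(f"{name} pool lacks classes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    q = ratio / (1.0 - ratio)  # target real:synthetic count ratio
    if len(real) / len(synthetic) > q:          # too much real data
        n_s = len(synthetic)
        n_r = int(round(q * n_s))
    else:                                        # too much synthetic data
        n_r = len(real)
        n_s = int(round(n_r / q))
    real_part = real if n_r == len(real) else _stratified_take(real, n_r, rng)
    synth_part = (synthetic if n_s == len(synthetic)
                  else _stratified_take(synthetic, n_s, rng))
    return real_part.concat(synth_part)


def mix_counts(real: LabeledDataset, synthetic: LabeledDataset,
               n_real: int, n_synthetic: int, seed: int = 0) -> LabeledDataset:
    """Absolute-count composition (e.g. 300 real + 2700 synthetic).

    Each pool is subsampled (seeded, class-balanced) to the exact count.
    """
    if n_real < 0 or n_synthetic < 0 or n_real + n_synthetic == 0:
        raise DatasetError("counts must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    parts = []
    if n_real:
        parts.append(real if n_real == len(real)
                     else _stratified_take(real, n_real, rng))
    if n_synthetic:
        parts.append(synthetic if n_synthetic == len(synthetic)
                     else _stratified_take(synthetic, n_synthetic, rng))
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    return out


# -- hold-out split ------------------------------------------------------------

def holdout_split(ds: LabeledDataset, train_frac: float = 0.8,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/validation partition (default 80:20)."""
    if not 0.0 < train_frac < 1.0:
        raise DatasetError("train_frac must be in (0, 1)")
    counts = ds.class_counts()
    for lab, n in counts.items():
        if n < 2:
            raise DatasetError(f"class {lab!r} has fewer than 2 records")
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(ds))
    tr, va = train_test_split(idx, train_size=train_frac, random_state=seed,
                              stratify=np.asarray(ds.labels))
    return ds.subset(sorted(tr.tolist())), ds.subset(sorted(va.tolist()))


# -- relabeling ----------------------------------------------------------------

def relabel(ds: LabeledDataset, scheme: str) -> LabeledDataset:
    """Map records to a different label scheme using concentration metadata."""
    if scheme not in LABEL_SCHEMES:
        raise DatasetError(f"unknown scheme {scheme!r}")
    records = []
    for r in ds.records:
        conc = r.meta.get("concentration")
        if conc is None:
            raise DatasetError("record lacks concentration metadata")
        conc = float(conc)
        if scheme == "three_class":
            label = CONC_TO_CLASS[conc]
        elif scheme == "binary":
            label = "negative" if conc == 0.0 else "positive"
        else:  # five_level
            label = f"{conc:g}"
        records.append(Record(image=r.image, label=label,
                              provenance=r.provenance, meta=dict(r.meta),
                              ref=r.ref))
    return LabeledDataset(records)
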