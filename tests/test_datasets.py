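"""Dataset container, mixing, hold-out splits, label schemes, manifest I/O."""

import numpy as np
import pytest

from stripgan.datasets import (
    DatasetError,
    LabeledDataset,
    Record,
    holdout_split,
    mix,
    mix_counts,
    relabel,
)


def make_pool(n_per_class, provenance, rng, classes=("blank", "low", "high"),
              conc=None):
    concs = {"blank": 0.0, "low": 0.25, "high": 1.0}
    return LabeledDataset(
        Record(image=rng.random((3, 8, 8)), label=lab, provenance=provenance,
               meta={"concentration": concs[lab] if conc is None else conc})
        for lab in classes for _ in range(n_per_class))


def test_record_validation(rng):
    with pytest.raises(DatasetError):
        Record(image=rng.random((3, 8, 8)), label="low", provenance="fake")
    r = Record(image=rng.random((3, 8, 8)), label="low", provenance="real")
    with pytest.raises(DatasetError):
        LabeledDataset([r, r])  # duplicate refs


class TestMix:
    def test_balanced_pools_concatenate(self, rng):
        real = make_pool(5, "real", rng)
        synth = make_pool(5, "synthetic", rng)
        mixed = mix(real, synth, ratio=0.5, seed=0)
        assert len(mixed) == 30
        assert mixed.provenance_counts() == {"real": 15, "synthetic": 15}

    def test_oversupplied_pool_subsampled(self, rng):
        real = make_pool(30, "real", rng)      # 90 total
        synth = make_pool(10, "synthetic", rng)  # 30 total
        mixed = mix(real, synth, ratio=0.5, seed=1)
        assert mixed.provenance_counts() == {"real": 30, "synthetic": 30}
        counts = mixed.class_counts()
        assert counts == {"blank": 20, "low": 20, "high": 20}

    def test_missing_class_rejected(self, rng):
        real = make_pool(5, "real", rng)
        synth = make_pool(5, "synthetic", rng, classes=("low", "high"))
        with pytest.raises(DatasetError):
            mix(real, synth, ratio=0.5)

    def test_invalid_ratio_and_empty(self, rng):
        real = make_pool(2, "real", rng)
        synth = make_pool(2, "synthetic", rng)
        with pytest.raises(DatasetError):
            mix(real, synth, ratio=1.0)
        with pytest.raises(DatasetError):
            mix(LabeledDataset([]), synth)

    def test_absolute_counts_mode(self, rng):
        """The sparse-real compositions use exact counts (e.g. 10% real)."""
        real = make_pool(20, "real", rng)        # 60 available
        synth = make_pool(100, "synthetic", rng)  # 300 available
        mixed = mix_counts(real, synth, 30, 270, seed=2)
        assert len(mixed) == 300
        assert mixed.provenance_counts() == {"real": 30, "synthetic": 270}
        assert mixed.class_counts() == {"blank": 100, "low": 100, "high": 100}

    def test_counts_exceeding_pool_rejected(self, rng):
        real = make_pool(2, "real", rng)
        synth = make_pool(2, "synthetic", rng)
        with pytest.raises(DatasetError):
            mix_counts(real, synth, 100, 2)


class TestHoldout:
    def test_eighty_twenty_stratified(self, rng):
        ds = make_pool(100, "real", rng)
        train, val = holdout_split(ds, 0.8, seed=3)
        assert len(train) == 240 and len(val) == 60
        for counts in (train.class_counts(), val.class_counts()):
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_partition(self, rng):
        ds = make_pool(10, "real", rng)
        train, val = holdout_split(ds, 0.8, seed=4)
        train_refs = {r.ref for r in train}
        val_refs = {r.ref for r in val}
        assert train_refs | val_refs == {r.ref for r in ds}
        assert not train_refs & val_refs

    def test_determinism(self, rng):
        ds = make_pool(10, "real", rng)
        a = holdout_split(ds, 0.8, seed=5)
        b = holdout_split(ds, 0.8, seed=5)
        assert [r.ref for r in a[0]] == [r.ref for r in b[0]]

    def test_tiny_class_rejected(self, rng):
        ds = LabeledDataset([
            Record(image=rng.random((3, 8, 8)), label="blank",
                   provenance="real"),
            Record(image=rng.random((3, 8, 8)), label="low",
                   provenance="real"),
            Record(image=rng.random((3, 8, 8)), label="low",
                   provenance="real"),
        ])
        with pytest.raises(DatasetError):
            holdout_split(ds, 0.8, seed=0)


class TestRelabel:
    def test_three_class_mapping(self, rng):
        ds = make_pool(1, "real", rng, classes=("high",), conc=0.75)
        assert relabel(ds, "three_class").labels == ["high"]

    def test_binary_mapping(self, rng):
        for conc, expected in ((0.0, "negative"), (0.25, "positive"),
                               (1.0, "positive")):
            ds = LabeledDataset([Record(
                image=rng.random((3, 8, 8)), label="x", provenance="real",
                meta={"concentration": conc})])
            assert relabel(ds, "binary").labels == [expected]

    def test_five_level_histogram(self, rng):
        records = []
        for conc in (0.0, 0.25, 0.5, 0.75, 1.0):
            for _ in range(4):
                records.append(Record(image=rng.random((3, 8, 8)), label="x",
                                      provenance="real",
                                      meta={"concentration": conc}))
        ds = relabel(LabeledDataset(records), "five_level")
        assert set(ds.class_counts().values()) == {4}
        assert len(ds.class_counts()) == 5

    def test_missing_concentration_rejected(self, rng):
        ds = LabeledDataset([Record(image=rng.random((3, 8, 8)), label="x",
                                    provenance="real")])
        with pytest.raises(DatasetError):
            relabel(ds, "five_level")
        with pytest.raises(DatasetError):
            relabel(ds, "nonsense")


def test_manifest_roundtrip(tmp_path, rng):
    ds = make_pool(2, "real", rng)
    manifest = ds.save(tmp_path / "data")
    loaded = LabeledDataset.load(manifest)
    assert len(loaded) == len(ds)
    assert loaded.labels == ds.labels
    for a, b in zip(ds, loaded):
        assert a.provenance == b.provenance
        assert np.abs(a.image - b.image).max() <= 0.5 / 255 + 1e-12
        assert b.meta["concentration"] == a.meta["concentration"]
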