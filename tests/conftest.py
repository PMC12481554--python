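import numpy as np
import pytest

from stripgan import stripsim
from stripgan.datasets import LabeledDataset
from stripgan.gan import TOY_GAN, train


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_profile():
    return stripsim.TOY_PROFILE


@pytest.fixture(scope="session")
def toy_dataset():
    """120 simulated 16×16 strips, 40 per class."""
    return stripsim.sample_dataset(40, seed=1, profile=stripsim.TOY_PROFILE,
                                   height=16, width=16)


@pytest.fixture(scope="session")
def trained_toy_gans():
    """Three independently seeded toy GAN runs on high-concentration strips.

    Each entry holds the training set, generator, critic, loss history and
    config; shared across the stochastic training-behaviour tests so the
    expensive stage runs once.
    """
    runs = []
    for seed in (11, 12, 13):
        ds = stripsim.sample_dataset(100, seed=seed,
                                     profile=stripsim.TOY_PROFILE,
                                     height=16, width=16)
        high = LabeledDataset(r for r in ds if r.label == "high")
        cfg = TOY_GAN(seed=seed)
        gen, critic, history = train(high, cfg)
        runs.append({"seed": seed, "dataset": high, "generator": gen,
                     "critic": critic, "history": history, "cfg": cfg})
    return runs
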