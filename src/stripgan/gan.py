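"""Wasserstein GAN with an optional direct self-attention block.

The model pair follows the Wasserstein formulation: the critic maps an
image to an unbounded real score (no sigmoid), losses are logarithm-free
(critic minimizes mean(fake) − mean(real), generator minimizes
−mean(fake)), optimization uses RMSProp, and critic weights are clipped to
[−c, c] after every update to roughly enforce the 1-Lipschitz condition.
Disabling the attention block yields the plain WGAN baseline with an
identical training loop.

The generator is a U-Net over a noise-seeded 16×16 canvas: a dense layer
projects the latent vector to a canvas, a two-level convolutional encoder
compresses it, and a decoder with skip connections (and the attention
block at its deepest scale, when enabled) restores resolution; extra
upsampling blocks extend the output beyond 16×16.  Zero-padded
convolutions fix the boundary behaviour.  A final sigmoid bounds pixels
to [0, 1].

One unconditional model is trained per class label; class-labeled
synthetic data then comes from the matching generator.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import stripsim
from .attention import DirectSelfAttention, SAGANAttention
from .datasets import LabeledDataset, Record
from .nn import (
    Conv2d,
    Linear,
    Module,
    RMSProp,
    Tensor,
    concat_channels,
    no_grad,
    upsample_nearest,
)


class GANConfigError(ValueError):
    pass


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: "LossHistory"):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class GANConfig:
    noise_dim: int = 128
    image_size: int = 64
    base_channels: int = 32
    attention_enabled: bool = True
    sagan_attention: bool = False
    clip_value: float = 0.01
    critic_steps_per_gen: int = 5
    learning_rate: float = 5e-5
    batch_size: int = 32
    epochs: int = 10
    steps: int | None = None  # generator updates; overrides epochs if set
    seed: int = 0

    def __post_init__(self):
        s = self.image_size
        if s < 16 or (s & (s - 1)) != 0:
            raise GANConfigError("image_size must be a power of two >= 16")
        if self.clip_value <= 0:
            raise GANConfigError("clip_value must be > 0")
        if self.critic_steps_per_gen < 1:
            raise GANConfigError("critic_steps_per_gen must be >= 1")
        if self.noise_dim < 1 or self.base_channels < 1 or self.batch_size < 1:
            raise GANConfigError("noise_dim, base_channels, batch_size >= 1")


#: GAN profile used throughout the test-scale experiments: 16×16 strips,
#: narrow channels, few hundred updates — minutes on one CPU.  The learning
#: rate is raised above the full-scale default so the model reaches the
#: data distribution within the short toy schedule.
TOY_GAN = functools.partial(GANConfig, image_size=16, base_channels=8,
                            noise_dim=32, steps=200, learning_rate=2e-4)


@dataclass
class LossHistory:
    critic_loss: list[float] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    #: (generator step, empirical 1-Wasserstein distance between real and
    #: generated statistic marginals)
    wasserstein_monitor: list[tuple[int, float]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        n = max(len(self.critic_loss), len(self.generator_loss))
        mon = dict(self.wasserstein_monitor)
        pd.DataFrame({
            "step": np.arange(n),
            "critic_loss": pd.Series(self.critic_loss).reindex(range(n)),
            "generator_loss": pd.Series(self.generator_loss).reindex(range(n)),
            "wasserstein_monitor": pd.Series(
                [mon.get(i, np.nan) for i in range(n)]),
        }).to_csv(path, index=False)


def _attention_block(channels: int, cfg: GANConfig, rng) -> Module:
    cls = SAGANAttention if cfg.sagan_attention else DirectSelfAttention
    return cls(channels, rng)


class Generator(Module):
    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        b = cfg.base_channels
        self.cfg = cfg
        self.canvas = Linear(cfg.noise_dim, b * 16 * 16, rng)
        self.enc1 = Conv2d(b, 2 * b, 3, rng, stride=2)        # 16 -> 8
        self.enc2 = Conv2d(2 * b, 4 * b, 3, rng, stride=2)    # 8 -> 4
        self.dec1 = Conv2d(4 * b, 2 * b, 3, rng)              # at 8
        self.attention = (_attention_block(2 * b, cfg, rng)
                          if cfg.attention_enabled else None)
        self.dec1_merge = Conv2d(4 * b, 2 * b, 3, rng)
        self.dec2 = Conv2d(2 * b, b, 3, rng)                  # at 16
        self.dec2_merge = Conv2d(2 * b, b, 3, rng)
        n_extra = int(np.log2(cfg.image_size // 16))
        self.extra = [Conv2d(b, b, 3, rng) for _ in range(n_extra)]
        self.head = Conv2d(b, 3, 1, rng, pad=0)
        self.last_attention_map: np.ndarray | None = None

    def forward(self, z: Tensor) -> Tensor:
        b = self.cfg.base_channels
        n = z.shape[0]
        canvas = self.canvas(z).leaky_relu().reshape(n, b, 16, 16)
        e1 = self.enc1(canvas).leaky_relu()
        e2 = self.enc2(e1).leaky_relu()
        d1 = self.dec1(upsample_nearest(e2)).leaky_relu()
        if self.attention is not None:
            d1, amap = self.attention(d1)
            self.last_attention_map = amap.data
        d1 = self.dec1_merge(concat_channels(d1, e1)).leaky_relu()
        d2 = self.dec2(upsample_nearest(d1)).leaky_relu()
        d2 = self.dec2_merge(concat_channels(d2, canvas)).leaky_relu()
        for conv in self.extra:
            d2 = conv(upsample_nearest(d2)).leaky_relu()
        return self.head(d2).sigmoid()


class Critic(Module):
    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        b = cfg.base_channels
        self.cfg = cfg
        n_down = int(np.log2(cfg.image_size // 4))
        chans = [3] + [min(b * 2**i, 4 * b) for i in range(n_down)]
        self.blocks = [Conv2d(chans[i], chans[i + 1], 3, rng, stride=2)
                       for i in range(n_down)]
        self.attention = (_attention_block(chans[1], cfg, rng)
                          if cfg.attention_enabled else None)
        self.out = Linear(chans[-1] * 16, 1, rng)
        self.last_attention_map: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.blocks[0](x).leaky_relu()
        if self.attention is not None:
            h, amap = self.attention(h)
            self.last_attention_map = amap.data
        for block in self.blocks[1:]:
            h = block(h).leaky_relu()
        n = h.shape[0]
        return self.out(h.reshape(n, -1))


def build_generator(cfg: GANConfig) -> Generator:
    """Deterministically initialized generator (seeded from cfg.seed)."""
    return Generator(cfg, np.random.default_rng(cfg.seed))


def build_critic(cfg: GANConfig) -> Critic:
    return Critic(cfg, np.random.default_rng(cfg.seed + 1))


# -- losses --------------------------------------------------------------------

def critic_loss(real_scores, fake_scores):
    """Logarithm-free critic objective: mean(fake) − mean(real)."""
    real_scores = _scores(real_scores)
    fake_scores = _scores(fake_scores)
    return fake_scores.mean() - real_scores.mean()


def generator_loss(fake_scores):
    """Generator objective: −mean(fake)."""
    return -_scores(fake_scores).mean()


def _scores(s) -> Tensor:
    t = s if isinstance(s, Tensor) else Tensor(s)
    if t.data.size == 0:
        raise ValueError("empty score batch")
    return t


def wasserstein_1d(a, b) -> float:
    """Exact empirical 1-Wasserstein distance between two sample vectors.

    For equal sample counts this equals the mean absolute difference of
    sorted samples (minimum-cost assignment); otherwise it is the integral
    of the quantile-function gap.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample vector")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite samples")
    from scipy.stats import wasserstein_distance

    return float(wasserstein_distance(a, b))


# -- training ------------------------------------------------------------------

def _default_monitor_stat(img: np.ndarray) -> float:
    return stripsim.band_contrast(img, stripsim.TOY_PROFILE)


def train(dataset: LabeledDataset, cfg: GANConfig,
          monitor_stat=_default_monitor_stat,
          monitor_every: int = 20,
          ) -> tuple[Generator, Critic, LossHistory]:
    """WGAN training loop with weight clipping and RMSProp.

    Alternates ``critic_steps_per_gen`` critic updates (each followed by
    clipping all critic weights to [−clip_value, clip_value]) with one
    generator update.  ``monitor_stat`` maps an image to a scalar; the
    1-Wasserstein distance between its marginal over (up to 256) real
    images and over a generated batch is recorded in the history at
    initialization, every ``monitor_every`` generator steps, and at the
    end.  Fully reproducible from cfg.seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    images = dataset.images()
    s = cfg.image_size
    if images.shape[1:] != (3, s, s):
        raise GANConfigError(
            f"dataset images {images.shape[1:]} do not match config "
            f"image_size {s}")
    gen = build_generator(cfg)
    critic = build_critic(cfg)
    opt_g = RMSProp(gen.parameters(), lr=cfg.learning_rate)
    opt_c = RMSProp(critic.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 2)
    history = LossHistory()

    n = images.shape[0]
    bs = min(cfg.batch_size, n)
    if cfg.steps is not None:
        gen_steps = cfg.steps
    else:
        gen_steps = cfg.epochs * max(1, n // (bs * cfg.critic_steps_per_gen))

    mon_idx = rng.choice(n, size=min(256, n), replace=False)
    real_stats = np.array([monitor_stat(images[i]) for i in mon_idx])

    def record_monitor(step: int) -> None:
        with no_grad():
            z = Tensor(rng.standard_normal((64, cfg.noise_dim)))
            fake = gen(z).data
        fake_stats = np.array([monitor_stat(f) for f in fake])
        history.wasserstein_monitor.append(
            (step, wasserstein_1d(real_stats, fake_stats)))

    record_monitor(0)
    for step in range(1, gen_steps + 1):
        for _ in range(cfg.critic_steps_per_gen):
            idx = rng.choice(n, size=bs, replace=False)
            real = Tensor(images[idx])
            with no_grad():
                z = Tensor(rng.standard_normal((bs, cfg.noise_dim)))
                fake = Tensor(gen(z).data)
            loss_c = critic_loss(critic(real), critic(fake))
            if not np.isfinite(loss_c.data):
                raise TrainingDiverged("critic loss non-finite", history)
            opt_c.zero_grad()
            loss_c.backward()
            opt_c.step()
            for p in opt_c.params:
                np.clip(p.data, -cfg.clip_value, cfg.clip_value, out=p.data)
            history.critic_loss.append(float(loss_c.data))
        z = Tensor(rng.standard_normal((bs, cfg.noise_dim)))
        loss_g = generator_loss(critic(gen(z)))
        if not np.isfinite(loss_g.data):
            raise TrainingDiverged("generator loss non-finite", history)
        opt_g.zero_grad()
        opt_c.zero_grad()  # discard critic grads from this pass
        loss_g.backward()
        opt_g.step()
        history.generator_loss.append(float(loss_g.data))
        if step % monitor_every == 0 or step == gen_steps:
            record_monitor(step)
    return gen, critic, history


def generate(generator: Generator, n: int, seed: int,
             class_label: str = "blank") -> LabeledDataset:
    """Sample ``n`` synthetic images from a trained generator (seeded)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    cfg = generator.cfg
    with no_grad():
        for start in range(0, n, 256):
            count = min(256, n - start)
            z = Tensor(rng.standard_normal((count, cfg.noise_dim)))
            batch = np.clip(generator(z).data, 0.0, 1.0)
            for i in range(count):
                records.append(Record(image=batch[i], label=class_label,
                                      provenance="synthetic",
                                      meta={"gan_seed": seed,
                                            "index": start + i}))
    return LabeledDataset(records)


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: Module, cfg: GANConfig, path, step: int = 0) -> None:
    """Weights as .npz plus a JSON metadata sidecar (config, seed, step)."""
    path = Path(path)
    np.savez(path, *[p.data for p in model.parameters()])
    meta = {"config": dataclasses.asdict(cfg), "seed": cfg.seed, "step": step}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path, kind: str = "generator") -> tuple[Module, GANConfig]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = GANConfig(**meta["config"])
    model = build_generator(cfg) if kind == "generator" else build_critic(cfg)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state([data[k] for k in data.files])
    return model, cfg
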