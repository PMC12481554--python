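"""Similarity-based quality control of generated images.

GAN samplers prone to mode collapse can emit near-duplicate images; mixing
those into training data adds volume without diversity.  The filter walks
candidates in order and rejects any image that is too similar to an
already-accepted one under either of two complementary measures:

* **SSIM** (structural similarity, Gaussian-weighted 11×11 windows,
  σ = 1.5): 1 means structurally identical; a candidate is rejected when
  SSIM against an accepted image exceeds ``ssim_max``.
* **Hamming distance between 64-bit average hashes**: small distances mean
  near-duplicate global structure; a candidate is rejected when the
  distance to an accepted image falls below ``hamming_min``.

Thresholds default to ssim_max = 0.95 and hamming_min = 4 — conservative
dedup that removes copies while keeping ordinary sample-to-sample
variation.  By default both measures are evaluated exactly for every
candidate/accepted pair, so the accepted set provably contains no pair
violating either threshold; an optional hash prefilter skips the SSIM
computation for clearly-distant pairs, trading that exactness for speed
on large candidate pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .datasets import LabeledDataset


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    ssim_max: float = 0.95
    hamming_min: int = 4
    hash_bits: int = 64

    def __post_init__(self):
        if not 0.0 < self.ssim_max <= 1.0:
            raise QCError("ssim_max must be in (0, 1]")
        if self.hamming_min < 0:
            raise QCError("hamming_min must be >= 0")
        side = int(round(self.hash_bits ** 0.5))
        if side * side != self.hash_bits:
            raise QCError("hash_bits must be a perfect square")


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity between two 3×H×W images in [0, 1].

    Gaussian-weighted 11×11 windows (σ = 1.5), the canonical stability
    constants at data range 1, averaged over channels.  Symmetric, and
    exactly 1 for identical inputs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise QCError(f"shape mismatch: {a.shape} vs {b.shape}")
    win = min(11, a.shape[1] - (a.shape[1] + 1) % 2,
              a.shape[2] - (a.shape[2] + 1) % 2)
    return float(structural_similarity(
        a, b, channel_axis=0, data_range=1.0, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False, win_size=win))


def avg_hash(img: np.ndarray, bits: int = 64) -> np.ndarray:
    """Perceptual average hash: grayscale → √bits×√bits → threshold at mean.

    Returns a flat boolean bit vector of length ``bits``.
    """
    side = int(round(bits ** 0.5))
    if side * side != bits:
        raise QCError("bits must be a perfect square")
    gray = np.asarray(img, dtype=np.float64).mean(axis=0)
    small = resize(gray, (side, side), order=1, anti_aliasing=True,
                   preserve_range=True)
    return (small > small.mean()).ravel()


def hamming(h1: np.ndarray, h2: np.ndarray) -> int:
    """Number of differing bits between two hashes."""
    h1 = np.asarray(h1, dtype=bool)
    h2 = np.asarray(h2, dtype=bool)
    if h1.shape != h2.shape:
        raise QCError("hash length mismatch")
    return int(np.count_nonzero(h1 != h2))


def filter_generated(candidates: LabeledDataset,
                     thresholds: QCThresholds = QCThresholds(),
                     reference: LabeledDataset | None = None,
                     ssim_prefilter: bool = False,
                     ) -> tuple[LabeledDataset, pd.DataFrame]:
    """Greedy in-order dedup of generated images.

    A candidate is rejected iff, against any already-accepted image (plus
    the optional ``reference`` pool of real images), SSIM > ssim_max or
    Hamming distance < hamming_min.  With ``ssim_prefilter`` SSIM is only
    computed when the Hamming distance is below ``2 * hamming_min``.

    Returns the accepted subset and a per-image report with the rule that
    fired, the worst (highest) SSIM and the smallest Hamming distance seen.
    """
    if len(candidates) == 0:
        raise QCError("empty candidate set")
    accepted_idx: list[int] = []
    kept_images: list[np.ndarray] = []
    kept_hashes: list[np.ndarray] = []
    if reference is not None:
        for r in reference:
            kept_images.append(r.image)
            kept_hashes.append(avg_hash(r.image, thresholds.hash_bits))
    rows = []
    for i, rec in enumerate(candidates):
        h = avg_hash(rec.image, thresholds.hash_bits)
        best_ssim = -np.inf
        min_ham = thresholds.hash_bits + 1
        rule = ""
        for img_k, h_k in zip(kept_images, kept_hashes):
            d = hamming(h, h_k)
            min_ham = min(min_ham, d)
            if d < thresholds.hamming_min:
                rule = rule or "hamming"
            if ssim_prefilter and d >= 2 * thresholds.hamming_min:
                continue
            s = ssim(rec.image, img_k)
            best_ssim = max(best_ssim, s)
            if s > thresholds.ssim_max:
                rule = rule or "ssim"
        decision = "reject" if rule else "accept"
        if not rule:
            accepted_idx.append(i)
            kept_images.append(rec.image)
            kept_hashes.append(h)
        rows.append({
            "index": i,
            "ref": rec.ref,
            "decision": decision,
            "rule": rule,
            "best_ssim": best_ssim if np.isfinite(best_ssim) else np.nan,
            "min_hamming": min_ham if min_ham <= thresholds.hash_bits else np.nan,
        })
    report = pd.DataFrame(rows)
    return candidates.subset(accepted_idx), report
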