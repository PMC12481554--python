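"""Direct spatial self-attention with a learnable residual weight γ.

Classical GAN self-attention flattens the C×H×W feature map to compute an
(H·W)×(H·W) affinity matrix, which requires reshape/transpose passes over
the feature space.  The block here computes a single spatial attention map
directly: three 1×1 convolutions produce query, key and value features
f(x), g(x), v(x); the query and key are contracted over channels into one
score per position,

    s[h, w] = Σ_c f(x)[c, h, w] · g(x)[c, h, w],

softmax over all positions turns s into a map M (non-negative, summing
to 1), and the attended output is the value features reweighted per
position, o[c, h, w] = H·W · M[h, w] · v(x)[c, h, w] (the H·W factor keeps
o on the scale of v under a uniform map).  The result enters a residual,

    y = γ · o + x,

where γ is a learnable scalar initialized to exactly 0, so a freshly
constructed block is a bit-exact identity and attention blends in only as
training moves γ away from 0.

The forward path uses only 1×1 convolutions, pointwise products and axis
reductions — no flattening — so M is directly exportable as an H×W
heat map.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, Tensor, softmax
from .nn.autograd import stack0


class AttentionNumericError(FloatingPointError):
    pass


class DirectSelfAttention(Module):
    """Spatial attention map + γ-residual over a C×H×W feature map."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.w_f = Conv2d(channels, channels, 1, rng, pad=0)
        self.w_g = Conv2d(channels, channels, 1, rng, pad=0)
        self.w_v = Conv2d(channels, channels, 1, rng, pad=0)
        self.gamma = Tensor(np.zeros(()), requires_grad=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (y, map): y = γ·o + x and the (N,1,H,W) attention map."""
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        if not np.isfinite(x.data).all():
            raise AttentionNumericError("non-finite activations entering "
                                        "attention block")
        f = self.w_f(x)
        g = self.w_g(x)
        v = self.w_v(x)
        scores = (f * g).sum(axis=1, keepdims=True)
        amap = softmax(scores, axis=(2, 3))
        n_pos = float(x.shape[2] * x.shape[3])
        o = amap * v * n_pos
        y = self.gamma * o + x
        return y, amap


class SAGANAttention(Module):
    """Classical flattened N×N self-attention, kept for ablation runs.

    Computes the full position-by-position affinity matrix
    softmax(f(x)ᵀ g(x)) and applies it to v(x).  Quadratic in H·W.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.w_f = Conv2d(channels, channels, 1, rng, pad=0)
        self.w_g = Conv2d(channels, channels, 1, rng, pad=0)
        self.w_v = Conv2d(channels, channels, 1, rng, pad=0)
        self.gamma = Tensor(np.zeros(()), requires_grad=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        fb = self.w_f(x).reshape(n, c, h * w)
        gb = self.w_g(x).reshape(n, c, h * w)
        vb = self.w_v(x).reshape(n, c, h * w)
        outs, maps = [], []
        for i in range(n):
            # (hw, hw) affinity; each column is a softmax distribution
            aff = softmax(gb.select(i).T @ fb.select(i), axis=0)
            outs.append(vb.select(i) @ aff)
            maps.append(aff.mean(axis=1))
        o = stack0(outs).reshape(n, c, h, w)
        amap = stack0(maps).reshape(n, 1, h, w)
        y = self.gamma * o + x
        return y, amap


def attention_map(block: DirectSelfAttention, x: np.ndarray) -> np.ndarray:
    """Evaluate the block's H×W attention map for one feature map.

    The returned map is non-negative and sums to 1, suitable for heat-map
    export.
    """
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    _, amap = block(Tensor(arr))
    return amap.data[0, 0]


def save_attention_map(amap: np.ndarray, png_path=None, csv_path=None) -> None:
    """Export an attention map as a PNG heat map and/or CSV matrix."""
    if csv_path is not None:
        np.savetxt(csv_path, amap, delimiter=",")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(amap, cmap="magma")
        fig.colorbar(im, ax=ax)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(png_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
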