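"""Regression head: weight removal, weighted pooling, coordinate MLP.

The encoder output still carries the learnable patch-weight channel.  The
head splits it off, forms a weight-modulated global average over patches,
feature_d = (Σ_j w_j · t_{j,d}) / J, and regresses the pupil-center
coordinates (x̂, ŷ) in pixels with a two-layer SiLU MLP.  With uniform
unit weights the pooling is exactly global average pooling.

``pool_norm='count'`` divides by J (linear in the weights, stable gradient
scale); ``'weight_sum'`` divides by Σ_j w_j instead.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

POOL_NORMS = ("count", "weight_sum")


def remove_weights(fused):
    """Split the fused B×J×(D+1) sequence into (tokens B×J×D, weights B×J)."""
    if isinstance(fused, Tensor):
        if fused.shape[-1] < 2:
            raise ValueError("fused feature width must be >= 2")
        return fused[..., :-1], fused[..., -1]
    fused = np.asarray(fused, dtype=np.float64)
    if fused.shape[-1] < 2:
        raise ValueError("fused feature width must be >= 2")
    return fused[..., :-1], fused[..., -1]


def weighted_pool(tokens, weights, pool_norm: str = "count"):
    """Weight-modulated global average over patches: B×J×D → B×D."""
    if pool_norm not in POOL_NORMS:
        raise ValueError(f"unknown pool_norm {pool_norm!r}; expected one of {POOL_NORMS}")
    tensor_path = isinstance(tokens, Tensor) or isinstance(weights, Tensor)
    if tensor_path:
        tokens = ad.as_tensor(tokens)
        weights = ad.as_tensor(weights)
        B, J, D = tokens.shape
        if weights.shape[-1] != J:
            raise ValueError(f"weight length {weights.shape[-1]} != J={J}")
        w = weights if weights.ndim == 2 else weights.reshape((1, J))
        num = (tokens * w.reshape((-1, J, 1))).sum(axis=1)
        if pool_norm == "count":
            return num * (1.0 / J)
        return num * (w.sum(axis=-1, keepdims=True) ** -1.0)
    tokens = np.asarray(tokens, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    B, J, D = tokens.shape
    if weights.shape[-1] != J:
        raise ValueError(f"weight length {weights.shape[-1]} != J={J}")
    w = weights if weights.ndim == 2 else weights[None, :]
    num = np.einsum("bjd,bj->bd", tokens, np.broadcast_to(w, (B, J)))
    if pool_norm == "count":
        return num / J
    return num / w.sum(axis=-1, keepdims=True)


def mlp_head(feature: np.ndarray, W1, b1, W2, b2) -> np.ndarray:
    """Functional two-layer SiLU MLP mapping B×D features to B×2 pixels."""
    feature = np.asarray(feature, dtype=np.float64)
    hidden = feature @ np.asarray(W1) + np.asarray(b1)
    hidden = hidden * (1.0 / (1.0 + np.exp(-hidden)))
    return hidden @ np.asarray(W2) + np.asarray(b2)


class RegressionHead:
    """Weight removal + weighted pooling + MLP, as a trainable module."""

    def __init__(self, embed_dim: int, hidden: int | None = None,
                 pool_norm: str = "count",
                 rng: np.random.Generator | None = None,
                 output_offset: tuple[float, float] = (0.0, 0.0),
                 output_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        hidden = hidden or max(embed_dim // 2, 2)
        self.pool_norm = pool_norm
        # fixed affine output map: prediction = offset + scale * mlp(x).
        # Parameterizing the prediction as a scaled offset from the image
        # center keeps the network output O(1) while the loss stays in
        # pixels, so the optimizer does not spend thousands of steps
        # dragging the output bias up to pixel magnitudes.
        self.output_offset = np.asarray(output_offset, dtype=np.float64)
        self.output_scale = float(output_scale)
        self.W1 = Tensor(rng.normal(0.0, embed_dim ** -0.5, size=(embed_dim, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(rng.normal(0.0, hidden ** -0.5, size=(hidden, 2)), requires_grad=True)
        self.b2 = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def __call__(self, fused: Tensor) -> Tensor:
        tokens, weights = remove_weights(fused)
        pooled = weighted_pool(tokens, weights, pool_norm=self.pool_norm)
        hidden = ad.silu(pooled @ self.W1 + self.b1)
        out = hidden @ self.W2 + self.b2
        return out * self.output_scale + Tensor(self.output_offset)
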