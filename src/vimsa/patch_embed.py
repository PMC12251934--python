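"""Patch extraction, linear token embedding, and weighted feature fusion.

An h×w single-channel image is tiled into J = (h/p)·(w/p) non-overlapping
p×p patches in row-major order, each flattened (row-major pixel order) and
linearly projected to a D-dimensional token; a learnable J×D positional
table is added.  One learnable scalar weight per patch is then concatenated
as an extra feature channel, giving the fused B×J×(D+1) sequence the
encoder operates on.  The weight lets the model learn each patch's
contribution to the pupil-center regression at the cost of a single
channel rather than an attention sub-network.

Three weight initializations are supported: ``fixed`` (all ones),
``random`` (i.i.d. uniform on [1e-5, 1]) and ``gaussian`` — an isotropic
Gaussian bump over patch-center distance from the image center (peak 1,
spatial scale sigma_spatial; the default 15 px puts the central
30×30-pixel region within ±1 sigma) plus i.i.d. Gaussian noise so initial
weights are not tied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

WEIGHT_INIT_SCHEMES = ("fixed", "random", "gaussian")


@dataclass
class PatchSequence:
    """Flattened patches: values B×J×p², row-major patch and pixel order."""

    values: np.ndarray
    p: int
    grid_rows: int
    grid_cols: int

    @property
    def J(self) -> int:
        return self.grid_rows * self.grid_cols


def extract_patches(images, p: int) -> PatchSequence:
    """Tile images (B×h×w or h×w) into flattened p×p patches."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    B, h, w = images.shape
    if h % p != 0 or w % p != 0:
        raise ValueError(f"image size {h}x{w} not divisible by patch size p={p}")
    gr, gc = h // p, w // p
    # (B, gr, p, gc, p) -> (B, gr, gc, p, p) -> (B, J, p*p)
    tiles = images.reshape(B, gr, p, gc, p).transpose(0, 1, 3, 2, 4)
    return PatchSequence(tiles.reshape(B, gr * gc, p * p), p, gr, gc)


def assemble_patches(patches: PatchSequence) -> np.ndarray:
    """Inverse of :func:`extract_patches` (exact bijection)."""
    B, J, pp = patches.values.shape
    p, gr, gc = patches.p, patches.grid_rows, patches.grid_cols
    tiles = patches.values.reshape(B, gr, gc, p, p).transpose(0, 1, 3, 2, 4)
    return tiles.reshape(B, gr * p, gc * p)


def embed_patches(patches: PatchSequence, projection: np.ndarray,
                  bias: np.ndarray | None = None,
                  pos: np.ndarray | None = None) -> np.ndarray:
    """Linear projection to D-dim tokens plus positional table: B×J×D."""
    vals = patches.values
    proj = np.asarray(projection, dtype=np.float64)
    if proj.shape[0] != vals.shape[-1]:
        raise ValueError(
            f"projection expects input width {proj.shape[0]}, patches have {vals.shape[-1]}")
    out = vals @ proj
    if bias is not None:
        out = out + np.asarray(bias)
    if pos is not None:
        pos = np.asarray(pos)
        if pos.shape != out.shape[1:]:
            raise ValueError(f"positional table {pos.shape} != token shape {out.shape[1:]}")
        out = out + pos
    return out


def patch_center_distances(grid_rows: int, grid_cols: int, p: int) -> np.ndarray:
    """Distance (px) from each patch center to the image center, row-major."""
    h, w = grid_rows * p, grid_cols * p
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(grid_rows) * p + (p - 1) / 2.0
    cols = np.arange(grid_cols) * p + (p - 1) / 2.0
    dy = rows[:, None] - cy
    dx = cols[None, :] - cx
    return np.sqrt(dx**2 + dy**2).reshape(-1)


def init_patch_weights(grid_rows: int, grid_cols: int, p: int, scheme: str,
                       rng: np.random.Generator | None = None,
                       sigma_spatial: float = 15.0,
                       sigma_noise: float = 0.1) -> np.ndarray:
    """Initial per-patch weights under one of the three schemes."""
    J = grid_rows * grid_cols
    if scheme == "fixed":
        return np.ones(J)
    rng = rng or np.random.default_rng(0)
    if scheme == "random":
        return rng.uniform(1e-5, 1.0, size=J)
    if scheme == "gaussian":
        d = patch_center_distances(grid_rows, grid_cols, p)
        bump = np.exp(-(d**2) / (2.0 * sigma_spatial**2))
        return bump + rng.normal(0.0, sigma_noise, size=J)
    raise ValueError(f"unknown weight init scheme {scheme!r}; expected one of {WEIGHT_INIT_SCHEMES}")


def concat_weights(tokens, weights):
    """Append the per-patch weight as the last feature channel: B×J×(D+1).

    The weight column is shared across the batch.  Works on ndarrays and on
    autodiff Tensors (training path).
    """
    if isinstance(tokens, Tensor) or isinstance(weights, Tensor):
        tokens = ad.as_tensor(tokens)
        weights = ad.as_tensor(weights)
        B, J, D = tokens.shape
        if weights.shape[-1] != J:
            raise ValueError(f"weight length {weights.shape[-1]} != J={J}")
        col = weights.reshape((1, J, 1)) * Tensor(np.ones((B, J, 1)))
        return ad.concat([tokens, col], axis=-1)
    tokens = np.asarray(tokens, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    B, J, D = tokens.shape
    if weights.shape[-1] != J:
        raise ValueError(f"weight length {weights.shape[-1]} != J={J}")
    col = np.broadcast_to(weights.reshape(1, J, 1), (B, J, 1))
    return np.concatenate([tokens, col], axis=-1)


class PatchEmbed:
    """Trainable patch embedding producing the fused B×J×(D+1) sequence."""

    def __init__(self, image_height: int, image_width: int, p: int, embed_dim: int,
                 weight_init: str = "gaussian",
                 rng: np.random.Generator | None = None,
                 sigma_spatial: float = 15.0, sigma_noise: float = 0.1):
        rng = rng or np.random.default_rng(0)
        if image_height % p != 0 or image_width % p != 0:
            raise ValueError(
                f"image size {image_height}x{image_width} not divisible by p={p}")
        self.p = p
        self.grid_rows = image_height // p
        self.grid_cols = image_width // p
        self.embed_dim = embed_dim
        self.proj = Tensor(rng.normal(0.0, (p * p) ** -0.5, size=(p * p, embed_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.pos = Tensor(rng.normal(0.0, 0.02, size=(self.J, embed_dim)), requires_grad=True)
        self.patch_weights = Tensor(
            init_patch_weights(self.grid_rows, self.grid_cols, p, weight_init, rng,
                               sigma_spatial=sigma_spatial, sigma_noise=sigma_noise),
            requires_grad=True)

    @property
    def J(self) -> int:
        return self.grid_rows * self.grid_cols

    def parameters(self) -> list[Tensor]:
        return [self.proj, self.bias, self.pos, self.patch_weights]

    def __call__(self, images: np.ndarray) -> Tensor:
        patches = extract_patches(images, self.p)
        tokens = Tensor(patches.values) @ self.proj + self.bias + self.pos
        return concat_weights(tokens, self.patch_weights)
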