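"""Multi-head self-attention with an FFT-accelerated matrix-product route.

Scaled dot-product attention softmax(Q·Kᵀ·scale)·V involves two matrix
products.  The inference route here evaluates both through the
outer-product/frequency-domain decomposition in :mod:`vimsa.fourier`; the
softmax is taken in the time domain on the reconstructed score matrix
("Temp Matrix").  A dense route computes the same quantity with ordinary
matrix products and is used during gradient-based training; the two routes
agree to floating-point tolerance and the test suite asserts it.

The scale in the softmax argument is 1/√d_head by default (`sqrt_head_dim`);
`sqrt_num_heads` divides by √(number of heads) instead, for the reading in
which d_k names the head count.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fourier import MultCounter, matmul_outer_fft

SCALE_MODES = ("sqrt_head_dim", "sqrt_num_heads")


def softmax_rows(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def scaled_dot_product_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    scale: float | None = None,
    impl: str = "fft",
    counter: MultCounter | None = None,
) -> np.ndarray:
    """Single-head attention on J×d matrices.

    ``impl='fft'`` routes both the Q·Kᵀ product and the product of the
    softmaxed score matrix with V through the frequency domain;
    ``impl='dense'`` uses plain matrix products.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if not (np.isfinite(Q).all() and np.isfinite(K).all() and np.isfinite(V).all()):
        raise FloatingPointError("non-finite attention inputs")
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValueError(f"incompatible attention shapes {Q.shape}, {K.shape}, {V.shape}")
    if scale is None:
        scale = 1.0 / np.sqrt(Q.shape[1])
    if impl == "fft":
        scores = matmul_outer_fft(Q, K.T, counter=counter) * scale
        temp = softmax_rows(scores)
        return matmul_outer_fft(temp, V, counter=counter)
    elif impl == "dense":
        temp = softmax_rows((Q @ K.T) * scale)
        return temp @ V
    raise ValueError(f"unknown attention impl {impl!r}")


def attention_scale(d_head: int, n_heads: int, scale_mode: str) -> float:
    if scale_mode == "sqrt_head_dim":
        return 1.0 / np.sqrt(d_head)
    if scale_mode == "sqrt_num_heads":
        return 1.0 / np.sqrt(n_heads)
    raise ValueError(f"unknown scale_mode {scale_mode!r}; expected one of {SCALE_MODES}")


class MultiHeadAttention:
    """Learned Q/K/V projections, per-head attention, output projection.

    Operates on B×J×M token tensors; the internal projection width equals
    the input width M.  During training the dense route runs under the
    autodiff tape; with ``impl='fft'`` the forward pass is computed through
    the Fourier route (inference path, no gradients).
    """

    def __init__(
        self,
        width: int,
        n_heads: int,
        scale_mode: str = "sqrt_head_dim",
        impl: str = "dense",
        rng: np.random.Generator | None = None,
    ):
        if width % n_heads != 0:
            raise ValueError(f"projection width {width} not divisible by n_heads {n_heads}")
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.n_heads = n_heads
        self.d_head = width // n_heads
        self.scale_mode = scale_mode
        self.impl = impl
        init = lambda *s: Tensor(rng.normal(0.0, s[0] ** -0.5, size=s), requires_grad=True)
        self.Wq, self.bq = init(width, width), Tensor(np.zeros(width), requires_grad=True)
        self.Wk, self.bk = init(width, width), Tensor(np.zeros(width), requires_grad=True)
        self.Wv, self.bv = init(width, width), Tensor(np.zeros(width), requires_grad=True)
        self.Wo, self.bo = init(width, width), Tensor(np.zeros(width), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv, self.Wo, self.bo]

    @property
    def scale(self) -> float:
        return attention_scale(self.d_head, self.n_heads, self.scale_mode)

    def __call__(self, tokens: Tensor, impl: str | None = None) -> Tensor:
        impl = impl or self.impl
        B, J, M = tokens.shape
        if M != self.width:
            raise ValueError(f"token width {M} != attention width {self.width}")
        if impl == "fft":
            out = self._forward_fft(tokens.data)
            return Tensor(out)
        q = tokens @ self.Wq + self.bq
        k = tokens @ self.Wk + self.bk
        v = tokens @ self.Wv + self.bv
        # B×J×M -> B×h×J×d
        split = lambda t: t.reshape((B, J, self.n_heads, self.d_head)).swapaxes(1, 2)
        q, k, v = split(q), split(k), split(v)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale
        attn = ad.softmax(scores, axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape((B, J, M))
        return ctx @ self.Wo + self.bo

    def _forward_fft(self, tokens: np.ndarray, counter: MultCounter | None = None) -> np.ndarray:
        B, J, M = tokens.shape
        q = tokens @ self.Wq.data + self.bq.data
        k = tokens @ self.Wk.data + self.bk.data
        v = tokens @ self.Wv.data + self.bv.data
        out = np.empty_like(tokens)
        for b in range(B):
            heads = []
            for h in range(self.n_heads):
                sl = slice(h * self.d_head, (h + 1) * self.d_head)
                heads.append(
                    scaled_dot_product_attention(
                        q[b, :, sl], k[b, :, sl], v[b, :, sl],
                        scale=self.scale, impl="fft", counter=counter,
                    )
                )
            out[b] = np.concatenate(heads, axis=1)
        return out @ self.Wo.data + self.bo.data
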