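"""Discrete Fourier transforms and the outer-product route to matrix products.

A product C = A·B (A: m×n, B: n×p) can be written as a sum of n rank-1
terms, C = Σ_k a_k ⊗ b_k, where a_k is the k-th column of A and b_k the
k-th row of B.  Because the 2-D DFT of an outer product factorizes,
ψ(a ⊗ b) = ψ(a) ⊗ ψ(b), each rank-1 term can be formed in the frequency
domain from two 1-D transforms; all n terms are accumulated there (the DFT
is linear) and a single 2-D inverse transform recovers the product.

``dft_naive`` is the O(N²) definition and serves as the oracle for the
radix-2 Cooley–Tukey ``fft_radix2``.  All transforms here are hand-rolled
on purpose: the decomposition itself is the object of study, including its
arithmetic-operation accounting (:func:`count_operations`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def next_pow2(n: int) -> int:
    """Smallest power of two >= n (>= 1)."""
    if n < 1:
        raise ValueError("length must be >= 1")
    return 1 << (int(n) - 1).bit_length()


def is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def dft_naive(x) -> np.ndarray:
    """Direct O(N²) discrete Fourier transform of the last axis.

    X_k = Σ_n x_n · exp(-i·2π·k·n/N).  Used as the correctness oracle for
    the fast transform; no padding is applied.
    """
    x = np.asarray(x, dtype=np.complex128)
    n = x.shape[-1]
    if n < 1:
        raise ValueError("dft_naive requires a non-empty input")
    k = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return x @ w.T


def fft_radix2(x, pad: bool = True) -> np.ndarray:
    """Radix-2 Cooley–Tukey FFT along the last axis.

    The recursion splits the sequence into even- and odd-indexed halves,
    X_k       = E_k + e^{-i2πk/N}·O_k
    X_{k+N/2} = E_k - e^{-i2πk/N}·O_k.
    Inputs whose length is not a power of two are zero-padded to the next
    power of two (``pad=False`` raises instead).
    """
    x = np.asarray(x, dtype=np.complex128)
    n = x.shape[-1]
    if n < 1:
        raise ValueError("fft_radix2 requires a non-empty input")
    if not is_pow2(n):
        if not pad:
            raise ValueError(f"length {n} is not a power of two")
        x = zero_pad(x, next_pow2(n))
    return _fft_rec(x)


def _fft_rec(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    if n == 1:
        return x.copy()
    even = _fft_rec(x[..., 0::2])
    odd = _fft_rec(x[..., 1::2])
    twiddle = np.exp(-2j * np.pi * np.arange(n // 2) / n)
    t = twiddle * odd
    return np.concatenate([even + t, even - t], axis=-1)


def ifft(X) -> np.ndarray:
    """Inverse FFT along the last axis (power-of-two length required)."""
    X = np.asarray(X, dtype=np.complex128)
    n = X.shape[-1]
    if not is_pow2(n):
        raise AssertionError(f"internal: inverse transform length {n} not a power of two")
    return np.conj(_fft_rec(np.conj(X))) / n


def zero_pad(x: np.ndarray, length: int) -> np.ndarray:
    n = x.shape[-1]
    if n == length:
        return np.asarray(x)
    if n > length:
        raise ValueError("cannot pad to a shorter length")
    pad_width = [(0, 0)] * (x.ndim - 1) + [(0, length - n)]
    return np.pad(x, pad_width)


def outer_product(a, b) -> np.ndarray:
    """Outer product (a ⊗ b)_{ij} = a_i · b_j."""
    a = np.asarray(a)
    b = np.asarray(b)
    return np.multiply.outer(a, b)


def matmul_outer_fft(A, B, counter: "MultCounter | None" = None) -> np.ndarray:
    """Matrix product via rank-1 decomposition evaluated in the frequency domain.

    Columns of A and rows of B are zero-padded to a common power-of-two
    length L, transformed, combined as frequency-domain outer products,
    accumulated over the shared index k, inverted once with a 2-D inverse
    transform, and cropped back to m×p.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("matmul_outer_fft expects 2-D operands")
    m, n = A.shape
    n2, p = B.shape
    if n != n2:
        raise ValueError(f"inner dimensions disagree: {A.shape} x {B.shape}")
    L = next_pow2(max(m, p))
    # ψ of every column of A and every row of B at the padded length
    FA = fft_radix2(zero_pad(A.T, L))          # (n, L): FA[k] = ψ(a_k)
    FB = fft_radix2(zero_pad(B, L))            # (n, L): FB[k] = ψ(b_k)
    # Σ_k ψ(a_k) ⊗ ψ(b_k), accumulated in the frequency domain
    acc = FA.T @ FB                            # (L, L)
    if counter is not None:
        counter.record_matmul_fft(m, n, p, L)
    # single 2-D inverse transform, then crop
    out = ifft(np.swapaxes(ifft(acc), -1, -2))
    return np.real(np.swapaxes(out, -1, -2))[:m, :p]


class MultCounter:
    """Counts real multiplications actually performed by the FFT route.

    A complex multiply is counted as 4 real multiplications; each radix-2
    FFT of length L performs (L/2)·log2(L) complex butterfly multiplies.
    """

    def __init__(self) -> None:
        self.mults = 0

    def record_matmul_fft(self, m: int, n: int, p: int, L: int) -> None:
        per_fft = 4 * (L // 2) * int(np.log2(L))
        n_ffts = 2 * n          # forward transforms of all a_k and b_k
        n_iffts = 2 * L         # row and column inverse transforms
        self.mults += (n_ffts + n_iffts) * per_fft
        self.mults += 4 * L * L * n  # frequency-domain accumulation


@dataclass(frozen=True)
class OpCountReport:
    """Arithmetic-operation accounting for an N×N matrix product.

    ``direct_*`` counts follow the textbook triple loop; ``claimed_*``
    evaluate the nominal complexity formulas N² + N·log₂N multiplications
    and N·log₂N additions often quoted for the FFT route.  ``measured_mults`` (optional)
    is an instrumented count from an actual run; the claimed formulas are
    reported as stated, not asserted against the measurement.
    """

    N: int
    direct_mults: int
    direct_adds: int
    claimed_mults: int
    claimed_adds: int
    measured_mults: int | None = None


def count_operations(N: int, measure: bool = False, rng: np.random.Generator | None = None) -> OpCountReport:
    """Operation counts for an N×N product (N must be a power of two)."""
    if not is_pow2(N):
        raise ValueError(f"N={N} is not a power of two")
    log2n = int(np.log2(N))
    measured = None
    if measure:
        rng = rng or np.random.default_rng(0)
        counter = MultCounter()
        matmul_outer_fft(rng.normal(size=(N, N)), rng.normal(size=(N, N)), counter=counter)
        measured = counter.mults
    return OpCountReport(
        N=N,
        direct_mults=N**3,
        direct_adds=N**3 - N**2,
        claimed_mults=N**2 + N * log2n,
        claimed_adds=N * log2n,
        measured_mults=measured,
    )
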