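"""Bidirectional state-space encoder over patch-token sequences.

Each block normalizes the fused token sequence, expands it through two
linear maps (x and z), runs the x stream through a forward and a backward
pipeline — token mixer (multi-head self-attention by default, optionally a
depthwise 1-D convolution as in the plain Vision-Mamba ablation), SiLU,
then a selective state-space scan — gates both directions with SiLU(z),
projects back to model width and adds a skip connection.

The scan realizes the discrete recurrence

    h_t = Ad_t ∘ h_{t-1} + Bd_t · x_t,     y_t = ⟨Cd_t, h_t⟩

per channel, with input-dependent (selective) discretization
Ad_t = exp(Δ_t·A), Bd_t = Δ_t·B_t: Δ_t is a softplus-activated linear map
of the token, B_t and C_t are linear maps of the token, and A is a trained
negative matrix stored in log space so that 0 < Ad_t < 1 for every finite
input (the zero-input state always decays).  The output reads the
post-update state, so y_1 already depends on x_1.

``ssm_scan`` is the sequential reference implementation (the normative
semantics); ``ssm_scan_selective`` is a fused tape primitive whose
hand-derived backward pass the tests check against finite differences and
whose forward pass is checked against ``ssm_scan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .autodiff import Tensor
from .attention import MultiHeadAttention


def silu(x):
    """SiLU activation f(x) = x·σ(x); accepts ndarray or Tensor."""
    if isinstance(x, Tensor):
        return ad.silu(x)
    x = np.asarray(x, dtype=np.float64)
    return x * _sigmoid(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def layer_norm(x, gain=None, bias=None, eps: float = 1e-5):
    """Feature-wise normalization over the last axis, optional affine."""
    if isinstance(x, Tensor) or isinstance(gain, Tensor) or isinstance(bias, Tensor):
        x = ad.as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + eps) ** -0.5
        if gain is not None:
            xn = xn * gain
        if bias is not None:
            xn = xn + bias
        return xn
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc / np.sqrt(var + eps)
    if gain is not None:
        xn = xn * np.asarray(gain)
    if bias is not None:
        xn = xn + np.asarray(bias)
    return xn


# ---------------------------------------------------------------------------
# state-space scan
# ---------------------------------------------------------------------------

def ssm_scan(x, Ad, Bd, Cd) -> np.ndarray:
    """Sequential reference evaluation of the discrete state-space recurrence.

    Parameters broadcast against (B, J, H, S) for Ad/Bd and (B, J, S) for
    Cd; ``x`` may be (J,), (J, H) or (B, J, H).  Returns y with the same
    shape as ``x``.  h_0 = 0 and y_t reads the post-update state.
    """
    x = np.asarray(x, dtype=np.float64)
    orig_ndim = x.ndim
    if x.ndim == 1:          # (J,): one sequence, one channel
        x = x[None, :, None]
    elif x.ndim == 2:        # (J, H): one sequence
        x = x[None]
    B, J, H = x.shape
    Ad = np.asarray(Ad, dtype=np.float64)
    Bd = np.asarray(Bd, dtype=np.float64)
    Cd = np.asarray(Cd, dtype=np.float64)
    S = max(
        Ad.shape[-1] if Ad.ndim else 1,
        Bd.shape[-1] if Bd.ndim else 1,
        Cd.shape[-1] if Cd.ndim else 1,
    )
    Ad = np.broadcast_to(Ad, (B, J, H, S))
    Bd = np.broadcast_to(Bd, (B, J, H, S))
    Cd = np.broadcast_to(Cd, (B, J, S))
    h = np.zeros((B, H, S))
    y = np.empty((B, J, H))
    for t in range(J):
        h = Ad[:, t] * h + Bd[:, t] * x[:, t, :, None]
        y[:, t] = np.einsum("bhs,bs->bh", h, Cd[:, t])
    if orig_ndim == 1:
        return y[0, :, 0]
    if orig_ndim == 2:
        return y[0]
    return y


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    return y + np.log(-np.expm1(-y))


class SSMParams:
    """Trainable generators of the input-dependent discrete SSM matrices.

    A is stored as A_log with A = -exp(A_log) (strictly negative, so the
    discrete transition Ad = exp(Δ·A) lies in (0, 1)).  Δ, B_t and C_t are
    linear functions of the incoming token of width H; the state has S
    channels per feature.
    """

    def __init__(self, width: int, state_size: int, rng: np.random.Generator):
        H, S = width, state_size
        self.width, self.state_size = H, S
        self.A_log = Tensor(np.log(np.tile(np.arange(1, S + 1, dtype=np.float64), (H, 1))),
                            requires_grad=True)
        self.Wd = Tensor(rng.normal(0.0, H ** -0.5, size=(H, H)), requires_grad=True)
        dt = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), size=H))
        self.bd = Tensor(_inv_softplus(dt), requires_grad=True)
        self.WB = Tensor(rng.normal(0.0, H ** -0.5, size=(H, S)), requires_grad=True)
        self.bB = Tensor(np.zeros(S), requires_grad=True)
        self.WC = Tensor(rng.normal(0.0, H ** -0.5, size=(H, S)), requires_grad=True)
        self.bC = Tensor(np.zeros(S), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.A_log, self.Wd, self.bd, self.WB, self.bB, self.WC, self.bC]

    def discretize(self, x: np.ndarray):
        """Per-timestep (Ad, Bd, Cd) for the reference scan; x: (B, J, H)."""
        delta = _softplus(x @ self.Wd.data + self.bd.data)          # (B,J,H)
        Bt = x @ self.WB.data + self.bB.data                        # (B,J,S)
        Ct = x @ self.WC.data + self.bC.data                        # (B,J,S)
        A = -np.exp(self.A_log.data)                                # (H,S)
        Ad = np.exp(delta[..., None] * A)                           # (B,J,H,S)
        Bd = delta[..., None] * Bt[:, :, None, :]                   # (B,J,H,S)
        return Ad, Bd, Ct


def ssm_scan_selective(x: Tensor, params: SSMParams) -> Tensor:
    """Fused selective scan: forward recurrence plus hand-derived backward."""
    xd = np.asarray(x.data, dtype=np.float64)
    B, J, H = xd.shape
    S = params.state_size
    A_log, Wd, bd = params.A_log, params.Wd, params.bd
    WB, bB, WC, bC = params.WB, params.bB, params.WC, params.bC

    with np.errstate(invalid="ignore"):
        pre = xd @ Wd.data + bd.data
        delta = _softplus(pre)                                      # (B,J,H)
        Bt = xd @ WB.data + bB.data                                 # (B,J,S)
        Ct = xd @ WC.data + bC.data                                 # (B,J,S)
    for name, arr in (("delta", delta), ("B", Bt), ("C", Ct)):
        if not np.isfinite(arr).all():
            t_bad = int(np.argwhere(~np.isfinite(arr).all(axis=-1))[0][1])
            raise FloatingPointError(
                f"non-finite SSM parameter {name} generated at timestep {t_bad}")
    A = -np.exp(A_log.data)                                         # (H,S)
    Ad = np.exp(delta[..., None] * A)                               # (B,J,H,S)
    Bx = delta * xd                                                 # (B,J,H)
    U = Bx[..., None] * Bt[:, :, None, :]                           # (B,J,H,S)
    hs = np.empty((B, J, H, S))
    AdJ = Ad.swapaxes(0, 1)                                         # (J,B,H,S)
    UJ = U.swapaxes(0, 1)
    hsJ = hs.swapaxes(0, 1)
    h = np.zeros((B, H, S))
    for t in range(J):
        np.multiply(h, AdJ[t], out=h)
        h += UJ[t]
        hsJ[t] = h
    y = (hs @ Ct[..., None])[..., 0]                                # (B,J,H)

    def backward(gy: np.ndarray):
        dCt = (gy[:, :, None, :] @ hs)[:, :, 0, :]                  # (B,J,S)
        gh_y = gy[..., None] * Ct[:, :, None, :]                    # (B,J,H,S)
        ghs = np.empty_like(hs)
        ghyJ = gh_y.swapaxes(0, 1)
        ghsJ = ghs.swapaxes(0, 1)
        carry = np.zeros((B, H, S))
        for t in range(J - 1, -1, -1):
            carry += ghyJ[t]
            ghsJ[t] = carry
            carry = AdJ[t] * carry
        hprev = np.concatenate([np.zeros((B, 1, H, S)), hs[:, :-1]], axis=1)
        ddA = ghs * hprev * Ad                                      # grad wrt Δ·A
        dBx = (ghs @ Bt[..., None])[..., 0]                         # (B,J,H)
        dBt = (Bx[:, :, None, :] @ ghs)[:, :, 0, :]                 # (B,J,S)
        ddelta = (ddA * A).sum(axis=-1) + dBx * xd
        dA = np.einsum("bjhs,bjh->hs", ddA, delta)
        dA_log = dA * A
        dx = dBx * delta
        dpre = ddelta * _sigmoid(pre)
        dx += dpre @ Wd.data.T + dBt @ WB.data.T + dCt @ WC.data.T
        flat = xd.reshape(-1, H)
        dWd = flat.T @ dpre.reshape(-1, H)
        dWB = flat.T @ dBt.reshape(-1, S)
        dWC = flat.T @ dCt.reshape(-1, S)
        return (
            (x, dx),
            (A_log, dA_log),
            (Wd, dWd), (bd, dpre.sum(axis=(0, 1))),
            (WB, dWB), (bB, dBt.sum(axis=(0, 1))),
            (WC, dWC), (bC, dCt.sum(axis=(0, 1))),
        )

    return ad.custom_op([x, *params.parameters()], y, backward)


# ---------------------------------------------------------------------------
# token mixers and directional paths
# ---------------------------------------------------------------------------

class DepthwiseConv1d:
    """Per-channel 1-D convolution over the sequence axis (plain-ViM mixer)."""

    def __init__(self, width: int, kernel_size: int, rng: np.random.Generator):
        self.kernel_size = kernel_size
        self.w = Tensor(rng.normal(0.0, kernel_size ** -0.5, size=(kernel_size, width)), requires_grad=True)
        self.b = Tensor(np.zeros(width), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor, impl: str | None = None) -> Tensor:
        xd = x.data
        B, J, H = xd.shape
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(xd, ((0, 0), (pad, pad - (1 - k % 2)), (0, 0)))
        y = self.b.data + sum(self.w.data[tau] * xp[:, tau:tau + J] for tau in range(k))
        w, b = self.w, self.b

        def backward(g):
            dw = np.stack([np.einsum("bjh,bjh->h", g, xp[:, tau:tau + J]) for tau in range(k)])
            gp = np.zeros_like(xp)
            for tau in range(k):
                gp[:, tau:tau + J] += self.w.data[tau] * g
            dx = gp[:, pad:pad + J]
            return ((x, dx), (w, dw), (b, g.sum(axis=(0, 1))))

        return ad.custom_op([x, w, b], y, backward)


class DirectionPath:
    """Mixer → SiLU → selective scan, optionally on the reversed sequence."""

    def __init__(self, width: int, state_size: int, n_heads: int, direction: str,
                 rng: np.random.Generator, scale_mode: str = "sqrt_head_dim",
                 mixer: str = "fmsa", conv_kernel: int = 3):
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {direction!r}")
        self.direction = direction
        if mixer == "fmsa":
            self.mixer = MultiHeadAttention(width, n_heads, scale_mode=scale_mode, rng=rng)
        elif mixer == "conv1d":
            self.mixer = DepthwiseConv1d(width, conv_kernel, rng)
        else:
            raise ValueError(f"unknown mixer {mixer!r}")
        self.ssm = SSMParams(width, state_size, rng)

    def parameters(self) -> list[Tensor]:
        return self.mixer.parameters() + self.ssm.parameters()

    def __call__(self, x: Tensor, impl: str | None = None) -> Tensor:
        if self.direction == "backward":
            x = ad.flip(x, axis=1)
        y = ssm_scan_selective(silu(self.mixer(x, impl=impl)), self.ssm)
        if self.direction == "backward":
            y = ad.flip(y, axis=1)
        return y


def direction_path(x, path: DirectionPath, impl: str | None = None) -> np.ndarray:
    """Functional wrapper: run a directional pipeline on an ndarray."""
    with ad.no_grad():
        return path(ad.as_tensor(x), impl=impl).data


# ---------------------------------------------------------------------------
# encoder blocks
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Stacked-encoder hyperparameters.

    ``model_width`` is the fused token width M = D+1.  ``hidden_width``
    defaults to 2·M rounded up to the next multiple of ``n_heads`` so the
    attention head split is exact.
    """

    model_width: int
    hidden_width: int | None = None
    state_size: int = 16
    n_layers: int = 4
    n_heads: int = 12
    scale_mode: str = "sqrt_head_dim"
    mixer: str = "fmsa"

    def __post_init__(self):
        if min(self.model_width, self.state_size, self.n_layers + 1, self.n_heads) < 1:
            raise ValueError("encoder config dimensions must be >= 1")
        if self.hidden_width is None:
            h = 2 * self.model_width
            self.hidden_width = -(-h // self.n_heads) * self.n_heads
        if self.hidden_width % self.n_heads != 0:
            raise ValueError(
                f"hidden_width {self.hidden_width} not divisible by n_heads {self.n_heads}")


class EncoderBlock:
    """One bidirectional gated block with skip connection."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        M, H = config.model_width, config.hidden_width
        self.config = config
        self.ln_gain = Tensor(np.ones(M), requires_grad=True)
        self.ln_bias = Tensor(np.zeros(M), requires_grad=True)
        self.Wx = Tensor(rng.normal(0.0, M ** -0.5, size=(M, H)), requires_grad=True)
        self.bx = Tensor(np.zeros(H), requires_grad=True)
        self.Wz = Tensor(rng.normal(0.0, M ** -0.5, size=(M, H)), requires_grad=True)
        self.bz = Tensor(np.zeros(H), requires_grad=True)
        kw = dict(scale_mode=config.scale_mode, mixer=config.mixer)
        self.fwd = DirectionPath(H, config.state_size, config.n_heads, "forward", rng, **kw)
        self.bwd = DirectionPath(H, config.state_size, config.n_heads, "backward", rng, **kw)
        self.Wout = Tensor(rng.normal(0.0, H ** -0.5, size=(H, M)), requires_grad=True)
        self.bout = Tensor(np.zeros(M), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return ([self.ln_gain, self.ln_bias, self.Wx, self.bx, self.Wz, self.bz,
                 self.Wout, self.bout]
                + self.fwd.parameters() + self.bwd.parameters())

    def __call__(self, tokens: Tensor, impl: str | None = None) -> Tensor:
        u = layer_norm(tokens, self.ln_gain, self.ln_bias)
        xs = u @ self.Wx + self.bx
        zs = u @ self.Wz + self.bz
        yf = self.fwd(xs, impl=impl)
        yb = self.bwd(xs, impl=impl)
        g = silu(zs)
        combined = g * yf + g * yb
        return combined @ self.Wout + self.bout + tokens


def encoder_block(tokens, block: EncoderBlock, impl: str | None = None) -> np.ndarray:
    """Functional wrapper: run one block on an ndarray without gradients."""
    with ad.no_grad():
        return block(ad.as_tensor(tokens), impl=impl).data


class Encoder:
    """``n_layers`` sequential blocks with independent parameters."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.blocks = [EncoderBlock(config, rng) for _ in range(config.n_layers)]

    def parameters(self) -> list[Tensor]:
        return [p for b in self.blocks for p in b.parameters()]

    def __call__(self, tokens: Tensor, impl: str | None = None) -> Tensor:
        for b in self.blocks:
            tokens = b(tokens, impl=impl)
        return tokens


def encoder_forward(tokens, encoder: Encoder, impl: str | None = None) -> np.ndarray:
    with ad.no_grad():
        return encoder(ad.as_tensor(tokens), impl=impl).data
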