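"""Differentiable layer primitives for the multi-domain EEG network.

Each primitive is a pure function returning ``(output, cache)`` with a
matching ``*_backward(grad_out, cache)`` returning input/parameter
gradients.  Everything runs in float64 numpy; the only heavy operation —
the temporal+spatial convolution pair — is evaluated in the frequency
domain after composing the two linear stages into one per-(output-map,
channel) kernel, which turns the dominant cost into small complex
einsums instead of a dense im2col matmul.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

LOG_EPS = 1e-6


# ---------------------------------------------------------------------------
# composed temporal (1 x K) + spatial (C x 1) convolution, "valid" in time
# ---------------------------------------------------------------------------

def composed_conv(x: np.ndarray, k_temporal: np.ndarray, w_spatial: np.ndarray):
    """Temporal then spatial convolution in one pass.

    x : (B, C, T) input crops.
    k_temporal : (F1, K) temporal filters (cross-correlation convention).
    w_spatial : (F2, F1, C) spatial mixing over temporal maps and channels.

    Equivalent to the two-layer form ``y[b,o] = Σ_m Σ_c w[o,m,c] (k_m ⋆
    x[b,c])`` with valid windows; output is (B, F2, T-K+1).
    """
    b, c, t = x.shape
    f2, f1, c2 = w_spatial.shape
    if c2 != c:
        raise ValueError(f"spatial kernel expects {c2} channels, input has {c}")
    k = k_temporal.shape[1]
    nfft = next_fast_len(t)
    xf = rfft(x, nfft, axis=-1)                                   # (B, C, F)
    kern = np.einsum("omc,mt->oct", w_spatial, k_temporal)        # (F2, C, K)
    kf = rfft(kern, nfft, axis=-1)                                # (F2, C, F)
    # per-frequency (O,C) @ (C,B) matmul == einsum("ocf,bcf->bof", kf*, xf)
    yf = (kf.conj().transpose(2, 0, 1) @ xf.transpose(2, 1, 0)).transpose(2, 1, 0)
    y = irfft(yf, nfft, axis=-1)[:, :, : t - k + 1]
    cache = (xf, kf, k_temporal, w_spatial, nfft, t, k)
    return y, cache


def composed_conv_backward(grad: np.ndarray, cache):
    xf, kf, k_temporal, w_spatial, nfft, t, k = cache
    gf = rfft(grad, nfft, axis=-1)                                # (B, F2, F)
    # d/dx: convolution of kernel with upstream gradient
    # einsum("ocf,bof->bcf", kf, gf) as per-frequency (C,O) @ (O,B)
    gxf = (kf.transpose(2, 1, 0) @ gf.transpose(2, 1, 0)).transpose(2, 1, 0)
    gx = irfft(gxf, nfft, axis=-1)[:, :, :t]
    # d/dkernel: correlation of upstream gradient with the input
    # einsum("bof,bcf->ocf", gf*, xf) as per-frequency (O,B) @ (B,C)
    gkf = (gf.conj().transpose(2, 1, 0) @ xf.transpose(2, 0, 1)).transpose(1, 2, 0)
    gkern = irfft(gkf, nfft, axis=-1)[:, :, :k]
    g_wsp = np.einsum("oct,mt->omc", gkern, k_temporal)
    g_kt = np.einsum("oct,omc->mt", gkern, w_spatial)
    return gx, g_kt, g_wsp


# ---------------------------------------------------------------------------
# batch normalization over (batch, time) per feature map
# ---------------------------------------------------------------------------

def batchnorm(x, gamma, beta, running, train: bool, momentum=0.1, eps=1e-5):
    """x: (B, F, U); normalizes each map over batch and time."""
    if train:
        mu = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None]) * ivar[None, :, None]
    y = gamma[None, :, None] * xhat + beta[None, :, None]
    return y, (xhat, ivar, gamma)


def batchnorm_backward(grad, cache):
    xhat, ivar, gamma = cache
    b, _, u = grad.shape
    nn = b * u
    g_gamma = np.einsum("bfu,bfu->f", grad, xhat)
    g_beta = grad.sum(axis=(0, 2))
    dxhat = grad * gamma[None, :, None]
    gx = (ivar[None, :, None] / nn) * (
        nn * dxhat
        - dxhat.sum(axis=(0, 2))[None, :, None]
        - xhat * g_gamma[None, :, None]
    )
    return gx, g_gamma, g_beta


# ---------------------------------------------------------------------------
# square -> average pool -> log, the band-power-like activation stack
# ---------------------------------------------------------------------------

def square(x):
    return x * x, x


def square_backward(grad, x):
    return 2.0 * x * grad


def avgpool1d(x, kernel: int, stride: int):
    """x: (B, F, U) -> (B, F, P) with P = floor((U - kernel)/stride) + 1."""
    u = x.shape[2]
    if kernel > u:
        raise ValueError(f"pool kernel {kernel} exceeds input length {u}")
    p = (u - kernel) // stride + 1
    y = np.empty(x.shape[:2] + (p,), dtype=x.dtype)
    for i in range(p):
        y[:, :, i] = x[:, :, i * stride : i * stride + kernel].mean(axis=2)
    return y, (x.shape, kernel, stride, p)


def avgpool1d_backward(grad, cache):
    shape, kernel, stride, p = cache
    gx = np.zeros(shape, dtype=grad.dtype)
    w = 1.0 / kernel
    for i in range(p):
        gx[:, :, i * stride : i * stride + kernel] += grad[:, :, i : i + 1] * w
    return gx


def log_act(x, eps: float = LOG_EPS):
    xc = np.maximum(x, eps)
    return np.log(xc), (xc, x > eps)


def log_act_backward(grad, cache):
    xc, open_mask = cache
    return grad * open_mask / xc


# ---------------------------------------------------------------------------
# dropout / linear / softmax cross-entropy
# ---------------------------------------------------------------------------

def dropout(x, rate: float, train: bool, rng: np.random.Generator):
    if not train or rate <= 0:
        return x, None
    mask = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.dtype)
    return x * mask, mask


def dropout_backward(grad, mask):
    return grad if mask is None else grad * mask


def linear(x, w, b):
    """x: (B, n_in), w: (n_out, n_in), b: (n_out,)."""
    return x @ w.T + b, (x, w)


def linear_backward(grad, cache):
    x, w = cache
    return grad @ w, grad.T @ x, grad.sum(axis=0)


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits, labels):
    """Mean cross-entropy and its logit gradient for integer labels."""
    p = softmax(logits)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return nll.mean(), grad / n, p
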