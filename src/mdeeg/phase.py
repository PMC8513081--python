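"""Phase-domain representation: instantaneous phase via the Hilbert transform.

The analytic signal z(k) = s(k) + j ŝ(k) = A(k) e^{jφ(k)} pairs a real
signal with its Hilbert transform; its angle φ(k) is the instantaneous
phase, which this pipeline feeds to the classifier as the phase-domain
image of each trial.  Two constructions are provided: the exact discrete
analytic signal via the FFT (zero the negative frequencies, double the
positive ones — the default, O(T log T)) and the direct discrete
convolution sum

    ŝ(k) = (2/π) Σ_{n : k−n odd} s(n) / (k − n)

which is O(T²), edge-truncated, and kept as the literal quadrature oracle.
Phase is the four-quadrant arctangent of (ŝ, s), wrapped to (−π, π];
no unwrapping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import DomainTensor, EpochSet


@dataclass
class AnalyticSignal:
    """Real/imaginary parts with derived amplitude and wrapped phase."""

    real: np.ndarray
    imag: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)

    @property
    def phase(self) -> np.ndarray:
        return _wrap(np.arctan2(self.imag, self.real))


def _wrap(phi: np.ndarray) -> np.ndarray:
    # arctan2 yields [-pi, pi]; fold the closed lower edge onto +pi
    return np.where(phi == -np.pi, np.pi, phi)


def hilbert_direct(s: np.ndarray) -> np.ndarray:
    """Direct discrete Hilbert transform by parity-split summation.

    For each output index k, sums s(n)/(k−n) over the n of opposite parity
    to k (so k−n is odd), truncated to the available samples, scaled by 2/π.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("input must be a non-empty 1-D signal")
    n = s.size
    k = np.arange(n)
    diff = k[:, None] - k[None, :]
    with np.errstate(divide="ignore"):
        kernel = np.where(diff % 2 == 1, 2.0 / (np.pi * diff), 0.0)
    return kernel @ s


def analytic_signal(s: np.ndarray, method: str = "fft") -> AnalyticSignal:
    """Analytic signal of a 1-D real signal.

    ``method="fft"`` uses the discrete analytic-signal construction (exact
    one-sided spectrum); ``method="direct"`` uses :func:`hilbert_direct` for
    the quadrature component.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 1 or s.size < 4:
        raise ValueError("input must be a 1-D signal with at least 4 samples")
    if np.isnan(s).any():
        raise ValueError("input contains NaN")
    if method == "fft":
        z = _sig.hilbert(s)
        return AnalyticSignal(real=z.real, imag=z.imag)
    if method == "direct":
        return AnalyticSignal(real=s.copy(), imag=hilbert_direct(s))
    raise ValueError(f"unknown method {method!r}; expected 'fft' or 'direct'")


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Wrapped instantaneous phase along ``axis`` (FFT analytic signal)."""
    z = _sig.hilbert(np.asarray(x, dtype=np.float64), axis=axis)
    return _wrap(np.arctan2(z.imag, z.real))


def phase_domain(epochs: EpochSet) -> DomainTensor:
    """Phase-domain tensor: per trial and channel instantaneous phase.

    Shape is preserved; values are radians in (−π, π].  Input should be
    band-limited (run the bandpass first) for the phase to be meaningful.
    """
    if np.isnan(epochs.data).any():
        raise ValueError("epochs contain NaN")
    phi = instantaneous_phase(epochs.data, axis=-1)
    return DomainTensor(phi, "phase", epochs.fs)
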