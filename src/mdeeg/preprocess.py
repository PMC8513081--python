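"""Frequency filtering, resampling and per-domain normalization.

The motor-imagery pipeline band-limits the signal (4–40 Hz bandpass, or a
38 Hz lowpass for the public benchmark) with a fourth-order zero-phase
Butterworth IIR filter, optionally notches line noise, downsamples to
250 Hz, and z-scores each channel with statistics fitted on training data
only.  "Fourth order" refers to the design order before forward–backward
application, so the effective magnitude response is eighth order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import DomainTensor, EpochSet

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """One filtering step.

    kind : {"bandpass", "lowpass", "notch"}
    band : (low, high) Hz for bandpass; a single cutoff / notch frequency
        (Hz) otherwise.
    order : design order (Butterworth) — ignored for the notch, which is a
        second-order IIR section with quality factor ``q``.
    zero_phase : apply forward–backward (zero group delay).
    """

    kind: str
    band: tuple[float, float] | float
    order: int = 4
    zero_phase: bool = True
    q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        edges = self.band if isinstance(self.band, (tuple, list)) else (self.band,)
        for e in edges:
            if not 0 < e < nyq:
                raise ValueError(f"filter edge {e} Hz outside (0, {nyq}) Hz at fs={fs}")
        if self.kind == "bandpass" and edges[0] >= edges[1]:
            raise ValueError(f"bandpass edges must satisfy low < high, got {self.band}")

    def to_dict(self) -> dict:
        band = list(self.band) if isinstance(self.band, (tuple, list)) else self.band
        return {"kind": self.kind, "band": band, "order": self.order,
                "zero_phase": self.zero_phase, "q": self.q}

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        band = d["band"]
        if isinstance(band, list):
            band = tuple(band)
        return cls(kind=d["kind"], band=band, order=d.get("order", 4),
                   zero_phase=d.get("zero_phase", True), q=d.get("q", 30.0))


def _design(spec: FilterSpec, fs: float):
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.band, spec.q, fs=fs)
        return signal.tf2sos(b, a)
    if spec.kind == "bandpass":
        return signal.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    return signal.butter(spec.order, spec.band, btype="lowpass", fs=fs, output="sos")


def apply_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Filter every trial and channel along time; shape is preserved."""
    spec.validate(epochs.fs)
    sos = _design(spec, epochs.fs)
    filt = signal.sosfiltfilt if spec.zero_phase else signal.sosfilt
    out = filt(sos, epochs.data, axis=-1)
    return EpochSet(out, epochs.labels.copy(), epochs.fs, list(epochs.class_names),
                    None if epochs.channel_names is None else list(epochs.channel_names))


def resample(epochs: EpochSet, target_fs: float) -> EpochSet:
    """Downsample with polyphase anti-alias filtering.

    ``target_fs`` must not exceed the current rate; equal rates return an
    unchanged copy.  Output length is ``round(samples * target_fs / fs)``.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs > epochs.fs:
        raise ValueError(f"target_fs {target_fs} exceeds current rate {epochs.fs}")
    if math.isclose(target_fs, epochs.fs):
        return EpochSet(epochs.data.copy(), epochs.labels.copy(), epochs.fs,
                        list(epochs.class_names),
                        None if epochs.channel_names is None else list(epochs.channel_names))
    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    out = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    expected = int(round(epochs.n_samples * target_fs / epochs.fs))
    out = out[..., :expected]  # resample_poly rounds up on ragged ratios
    return EpochSet(out, epochs.labels.copy(), float(target_fs), list(epochs.class_names),
                    None if epochs.channel_names is None else list(epochs.channel_names))


@dataclass
class NormStats:
    """Per-channel z-scoring statistics fitted on a training set."""

    mean: np.ndarray   # (channels,)
    scale: np.ndarray  # (channels,), clamped away from zero

    EPS = 1e-12


def normalize(tensor: DomainTensor, stats: NormStats | None = None) -> tuple[DomainTensor, NormStats]:
    """Per-channel z-scoring.

    With ``stats=None`` the mean and standard deviation of each channel are
    computed over all trials and samples of ``tensor`` (the fitting set) and
    returned alongside the normalized data; pass those stats back in to apply
    the same frozen transform to held-out data.  Zero-variance channels are
    clamped to a small epsilon and logged.
    """
    if stats is None:
        mean = tensor.data.mean(axis=(0, 2))
        scale = tensor.data.std(axis=(0, 2))
        degenerate = scale <= NormStats.EPS
        if degenerate.any():
            logger.warning("zero-variance channel(s) %s: scale clamped to epsilon",
                           np.nonzero(degenerate)[0].tolist())
            scale = np.where(degenerate, NormStats.EPS, scale)
        stats = NormStats(mean=mean, scale=scale)
    out = (tensor.data - stats.mean[None, :, None]) / stats.scale[None, :, None]
    return DomainTensor(out, tensor.domain, tensor.fs), stats
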