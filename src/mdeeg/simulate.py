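"""Synthetic motor-imagery-like EEG with known class structure.

Emulates a three-class lower-limb motor-imagery recording: 31 channels of
the 10-20 montage sampled at 500 Hz, 30 five-second trials per class.
Each class carries a narrow-band oscillatory signature (amplitude-
modulated band-limited noise with random phase per trial) on a small set
of motor-area channels, superimposed on spatially independent 1/f^α
background noise.  A dry/wet electrode contrast is emulated purely as an
SNR knob: the dry preset multiplies the background RMS by a fixed ratio
while the class signals are identical, mirroring the higher impedance and
lower SNR of gel-free electrodes.

What this generator does NOT emulate: volume conduction (no mixing matrix
by default), ocular/muscular artifacts, inter-subject variability, or
non-stationarity across a session — so pipeline results on this data
demonstrate correctness of the machinery, not expected accuracy on real
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .containers import EpochSet

MONTAGE_31 = [
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
    "C1", "C2", "C3", "C4", "Cz", "CP1", "CP2", "CP5", "CP6", "P3",
    "P4", "P7", "P8", "Pz", "TP9", "TP10", "O1", "O2", "Oz", "PO9", "PO10",
]

# (channel index, center Hz, bandwidth Hz, amplitude µV); motor-area
# channels C1/C2/C3/C4/Cz, one rhythm per class inside the 4-40 Hz band
DEFAULT_SIGNATURES: dict[int, list[tuple[int, float, float, float]]] = {
    0: [(14, 11.0, 2.0, 6.0), (10, 11.0, 2.0, 6.0)],  # gait: mu-band Cz/C1
    1: [(14, 23.0, 2.0, 6.0), (11, 23.0, 2.0, 6.0)],  # sit: beta-band Cz/C2
    2: [(12, 9.0, 2.0, 6.0), (13, 9.0, 2.0, 6.0)],    # rest: alpha idle C3/C4
}


@dataclass
class SynthConfig:
    n_channels: int = 31
    fs: float = 500.0
    trial_seconds: float = 5.0
    n_classes: int = 3
    trials_per_class: int = 30
    signatures: dict[int, list[tuple[int, float, float, float]]] | None = None
    background_alpha: float = 1.0
    background_rms: float = 5.0       # wet-preset background RMS, µV
    dry_wet_ratio: float = 3.0        # dry background RMS / wet background RMS
    snr_preset: str = "wet"
    class_names: tuple[str, ...] | None = None
    mixing: bool = False              # optional random spatial mixing of background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signatures is None:
            self.signatures = {c: list(v) for c, v in DEFAULT_SIGNATURES.items()
                               if c < self.n_classes}
        if self.class_names is None:
            base = ("gait", "sit", "rest")
            self.class_names = tuple(
                base[i] if i < len(base) else f"class{i}" for i in range(self.n_classes)
            )
        if self.snr_preset not in ("wet", "dry"):
            raise ValueError("snr_preset must be 'wet' or 'dry'")
        if self.dry_wet_ratio <= 1:
            raise ValueError("dry background must exceed wet background (ratio > 1)")
        for cls, sigs in self.signatures.items():
            for ch, f0, bw, amp in sigs:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"signature channel {ch} out of range for class {cls}")
                if not 4.0 < f0 < 40.0:
                    raise ValueError(
                        f"signature frequency {f0} Hz for class {cls} outside (4, 40) Hz"
                    )
                if amp < 0 or bw <= 0:
                    raise ValueError("signature amplitude must be >= 0 and bandwidth > 0")

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    def background_rms_for(self, preset: str) -> float:
        return self.background_rms * (self.dry_wet_ratio if preset == "dry" else 1.0)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise along the last axis via spectral shaping."""
    n_freq = n_samples // 2 + 1
    spec = rng.standard_normal(shape + (n_freq,)) + 1j * rng.standard_normal(shape + (n_freq,))
    scale = np.zeros(n_freq)
    scale[1:] = np.arange(1, n_freq, dtype=float) ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n_samples, axis=-1)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _narrowband(rng: np.random.Generator, n_samples: int, fs: float,
                f0: float, bw: float) -> np.ndarray:
    """Unit-RMS band-limited noise (random phase) centered at f0."""
    sos = _sig.butter(4, (max(f0 - bw / 2, 0.1), min(f0 + bw / 2, fs / 2 * 0.99)),
                      btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / np.sqrt((x**2).mean())


def _components(cfg: SynthConfig):
    """Deterministic (labels, class-signal tensor, unit-RMS background tensor)."""
    rng = np.random.default_rng(cfg.seed)
    n_tr, n_ch, n_sa = cfg.n_trials, cfg.n_channels, cfg.n_samples
    labels = rng.permutation(np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class))

    background = _pink_noise(rng, (n_tr, n_ch), n_sa, cfg.background_alpha)
    if cfg.mixing:
        mix = np.eye(n_ch) + 0.2 * rng.standard_normal((n_ch, n_ch))
        background = np.einsum("ij,tjs->tis", mix, background)
        rms = np.sqrt((background**2).mean(axis=-1, keepdims=True))
        background = background / np.maximum(rms, 1e-30)

    envelope = _sig.windows.hann(n_sa)
    signals = np.zeros((n_tr, n_ch, n_sa))
    for t in range(n_tr):
        for ch, f0, bw, amp in cfg.signatures.get(int(labels[t]), []):
            carrier = _narrowband(rng, n_sa, cfg.fs, f0, bw) * envelope
            rms = np.sqrt((carrier**2).mean())
            if rms > 0 and amp > 0:
                signals[t, ch] += carrier * (amp / np.sqrt(2.0)) / rms
    return labels, signals, background


def generate(cfg: SynthConfig) -> EpochSet:
    """Generate one session; deterministic under ``cfg.seed``."""
    labels, signals, background = _components(cfg)
    rms = cfg.background_rms_for(cfg.snr_preset)
    channel_names = MONTAGE_31 if cfg.n_channels == 31 else [
        f"ch{i}" for i in range(cfg.n_channels)
    ]
    return EpochSet(
        data=signals + rms * background,
        labels=labels,
        fs=cfg.fs,
        class_names=list(cfg.class_names),
        channel_names=list(channel_names),
    )


def generate_pair(cfg: SynthConfig) -> tuple[EpochSet, EpochSet]:
    """(wet, dry) sessions sharing identical class signals and trial order;
    only the background RMS differs, by ``cfg.dry_wet_ratio``."""
    labels, signals, background = _components(cfg)
    channel_names = MONTAGE_31 if cfg.n_channels == 31 else [
        f"ch{i}" for i in range(cfg.n_channels)
    ]
    def build(preset: str) -> EpochSet:
        return EpochSet(
            data=signals + cfg.background_rms_for(preset) * background,
            labels=labels.copy(),
            fs=cfg.fs,
            class_names=list(cfg.class_names),
            channel_names=list(channel_names),
        )
    return build("wet"), build("dry")
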