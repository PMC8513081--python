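"""Sliding-window crop augmentation with a crop→trial map.

Each trial is cut into overlapping windows (default 4 s every 0.1 s, so a
5-s trial yields 11 crops); the classifier trains on crops and per-trial
predictions are recovered by aggregating over each trial's crops.  Domain
transforms (CSP projection, analytic signal) are applied to the full trial
first and cropped afterwards, so all crops of a trial share one spatial
projection and one analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DomainTensor

_EPS = 1e-9  # guards float division, e.g. (5-4)/0.1 = 9.9999...


@dataclass
class CropSet:
    """Aligned windowed examples for each domain.

    ``domains`` maps a domain tag to a ``(crops_total, channels,
    window_samples)`` array; all domains use identical window offsets.
    ``trial_index[i]`` names the source trial of crop ``i``.
    """

    domains: dict[str, np.ndarray]
    labels: np.ndarray
    trial_index: np.ndarray
    window_seconds: float
    step_seconds: float
    fs: float

    @property
    def n_crops(self) -> int:
        return self.labels.size

    @property
    def n_trials(self) -> int:
        return int(self.trial_index.max()) + 1 if self.trial_index.size else 0

    def domain_list(self) -> list[str]:
        return list(self.domains)


def count_crops(trial_seconds: float, window_seconds: float, step_seconds: float) -> int:
    """Number of windows: floor((trial − window)/step) + 1."""
    if step_seconds <= 0:
        raise ValueError("step must be positive")
    if window_seconds > trial_seconds + _EPS:
        raise ValueError(
            f"window ({window_seconds}s) exceeds trial length ({trial_seconds}s)"
        )
    return int(np.floor((trial_seconds - window_seconds) / step_seconds + _EPS)) + 1


def make_crops(
    domains: dict[str, DomainTensor] | list[DomainTensor],
    labels: np.ndarray,
    window_seconds: float,
    step_seconds: float,
) -> CropSet:
    """Slice every domain tensor into aligned sliding windows.

    Window offsets are ``k * step`` seconds rounded to samples; at the
    standard rates (0.1 s at 250 Hz = 25 samples) rounding is exact and no
    drift occurs.
    """
    if not isinstance(domains, dict):
        domains = {d.domain: d for d in domains}
    if not domains:
        raise ValueError("need at least one domain tensor")
    tensors = list(domains.values())
    ref = tensors[0]
    for t in tensors[1:]:
        if t.data.shape != ref.data.shape or t.fs != ref.fs:
            raise ValueError(
                f"domain {t.domain!r} shape/fs {t.data.shape}/{t.fs} does not match "
                f"{ref.domain!r} {ref.data.shape}/{ref.fs}"
            )
    labels = np.asarray(labels)
    n_trials, _, n_samples = ref.data.shape
    if labels.shape != (n_trials,):
        raise ValueError("labels length must equal the number of trials")

    fs = ref.fs
    trial_seconds = n_samples / fs
    n_per = count_crops(trial_seconds, window_seconds, step_seconds)
    win = int(round(window_seconds * fs))
    offsets = np.array([int(round(k * step_seconds * fs)) for k in range(n_per)])
    if offsets[-1] + win > n_samples:
        raise ValueError("rounded crop offsets overrun the trial")

    out: dict[str, np.ndarray] = {}
    for name, tensor in domains.items():
        crops = np.stack([tensor.data[:, :, o : o + win] for o in offsets], axis=1)
        out[name] = crops.reshape(n_trials * n_per, ref.data.shape[1], win)
    return CropSet(
        domains=out,
        labels=np.repeat(labels, n_per),
        trial_index=np.repeat(np.arange(n_trials), n_per),
        window_seconds=window_seconds,
        step_seconds=step_seconds,
        fs=fs,
    )
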