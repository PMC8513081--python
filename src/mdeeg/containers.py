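"""Core data containers shared by every pipeline stage.

The universal currency is the :class:`EpochSet`: a labeled ``(trials,
channels, samples)`` tensor of epoched EEG in microvolts at a known
sampling rate.  A :class:`DomainTensor` is the same trial set re-expressed
in one of the three input domains (``time``, ``spatial``, ``phase``) and
always keeps the shape of the :class:`EpochSet` it derives from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMAINS = ("time", "spatial", "phase")


@dataclass
class RawRecording:
    """Continuous multichannel EEG with event markers.

    Parameters
    ----------
    data : ndarray, shape (channels, samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    events : list of (int, str)
        ``(sample_index, code)`` pairs; every index lies in ``[0, samples)``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a (channels, samples) matrix with at least one of each")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        n = self.data.shape[1]
        for i, (samp, code) in enumerate(self.events):
            if not 0 <= samp < n:
                raise ValueError(f"event {i} ({code!r}) at sample {samp} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Labeled epoched EEG: ``data`` is ``(trials, channels, samples)`` in µV."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    class_names: list[str]
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal the number of trials")
        m = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= m):
            raise ValueError(f"labels must lie in [0, {m})")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def select(self, idx) -> "EpochSet":
        """Return the sub-set of trials at ``idx`` (copy)."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            fs=self.fs,
            class_names=list(self.class_names),
            channel_names=None if self.channel_names is None else list(self.channel_names),
        )


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Pool several sessions into one trial set (e.g. before pooled CV).

    All sets must share sampling rate, channel count and class names.
    """
    if not sets:
        raise ValueError("need at least one EpochSet")
    first = sets[0]
    for s in sets[1:]:
        if s.fs != first.fs or s.n_channels != first.n_channels \
                or s.class_names != first.class_names:
            raise ValueError("epoch sets differ in fs, channels or classes")
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        fs=first.fs,
        class_names=list(first.class_names),
        channel_names=None if first.channel_names is None else list(first.channel_names),
    )


@dataclass
class DomainTensor:
    """One trial set expressed in a named input domain.

    Shape is identical to the source :class:`EpochSet`; ``domain`` is one of
    ``"time"``, ``"spatial"`` (CSP-projected) or ``"phase"`` (instantaneous
    phase in radians).
    """

    data: np.ndarray
    domain: str
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
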