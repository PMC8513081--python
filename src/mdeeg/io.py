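"""Reading epoched EEG from standard formats and the package's bundle format.

Continuous recordings come in as BrainVision triplets (.vhdr/.vmrk/.eeg),
GDF (the format of the public four-class motor-imagery benchmark) or EDF,
all via :mod:`mne`.  Epochs travel between pipeline stages as ``.npz``
bundles: a compressed array container with a JSON metadata block.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .containers import EpochSet, RawRecording

BUNDLE_VERSION = 1

_READERS = {"brainvision": "read_raw_brainvision", "gdf": "read_raw_gdf", "edf": "read_raw_edf"}


class FormatError(RuntimeError):
    """A file failed to parse under the named standard."""


def read_raw(path, format: str) -> RawRecording:
    """Read a continuous recording into a :class:`RawRecording` (µV).

    Parameters
    ----------
    path : path-like
        For BrainVision, the ``.vhdr`` header file.
    format : {"brainvision", "gdf", "edf"}

    Events are taken from the file's annotations as ``(sample_index,
    description)`` pairs; a file with no markers yields an empty event list.
    """
    import mne

    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader = getattr(mne.io, _READERS[format])
    try:
        raw = reader(str(path), preload=True, verbose="error")
    except Exception as exc:  # surface the offending header detail
        raise FormatError(f"could not parse {path.name} as {format}: {exc}") from exc

    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # mne returns SI volts
    events: list[tuple[int, str]] = []
    n = data_uv.shape[1]
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        samp = int(round((onset - raw.first_time) * fs))
        if 0 <= samp < n:
            events.append((samp, str(desc)))
    return RawRecording(data=data_uv, fs=fs, channel_names=list(raw.ch_names), events=events)


def extract_epochs(
    raw: RawRecording,
    cue_codes: dict[str, int],
    t_start: float,
    t_end: float,
    class_names: list[str] | None = None,
) -> EpochSet:
    """Cut cue-locked epochs out of a continuous recording.

    The window is half-open ``[cue + t_start, cue + t_end)`` in seconds,
    0-based sample indices; every epoch has exactly
    ``round((t_end - t_start) * fs)`` samples.
    """
    if not t_end > t_start:
        raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    n_samp = int(round((t_end - t_start) * raw.fs))
    starts, labels = [], []
    matched = 0
    for samp, code in raw.events:
        if code not in cue_codes:
            continue
        start = samp + int(round(t_start * raw.fs))
        if start < 0 or start + n_samp > raw.n_samples:
            raise ValueError(
                f"epoch window for cue {matched} (code {code!r}, sample {samp}) "
                f"extends outside the recording"
            )
        starts.append(start)
        labels.append(cue_codes[code])
        matched += 1
    if not starts:
        raise ValueError("no events matched the given cue codes")

    data = np.stack([raw.data[:, s : s + n_samp] for s in starts])
    if class_names is None:
        m = max(cue_codes.values()) + 1
        class_names = [f"class{i}" for i in range(m)]
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        fs=raw.fs,
        class_names=class_names,
        channel_names=list(raw.channel_names),
    )


def save_bundle(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` as a compressed ``.npz`` bundle."""
    meta = {
        "version": BUNDLE_VERSION,
        "fs": epochs.fs,
        "class_names": list(epochs.class_names),
        "channel_names": epochs.channel_names,
    }
    np.savez_compressed(
        path,
        data=epochs.data,
        labels=epochs.labels,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_bundle(path) -> EpochSet:
    """Load a bundle written by :func:`save_bundle`; bit-exact round trip."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]))
            data = npz["data"]
            labels = npz["labels"]
    except (zipfile.BadZipFile, OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path.name} is not a readable epoch bundle: {exc}") from exc
    version = meta.get("version")
    if version != BUNDLE_VERSION:
        raise FormatError(
            f"bundle version mismatch in {path.name}: file has {version}, "
            f"reader supports {BUNDLE_VERSION}"
        )
    return EpochSet(
        data=data,
        labels=labels,
        fs=meta["fs"],
        class_names=meta["class_names"],
        channel_names=meta["channel_names"],
    )
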