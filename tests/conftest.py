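"""Shared fixtures: small synthetic epoch sets and hand-rolled file writers.

The BrainVision and EDF writers below produce minimal but standard-
conforming files so the readers can be exercised round-trip without any
binary fixtures in the repository.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from mdeeg.containers import EpochSet, RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng) -> EpochSet:
    """30 trials x 4 channels x 200 samples, 3 balanced classes, 100 Hz."""
    data = rng.standard_normal((30, 4, 200))
    labels = np.tile(np.arange(3), 10)
    return EpochSet(data, labels, fs=100.0, class_names=["a", "b", "c"])


def write_brainvision(
    directory: Path,
    basename: str,
    data_uv: np.ndarray,
    fs: float,
    channel_names: list[str],
    markers: list[tuple[int, str, str]] = (),
) -> Path:
    """Write a minimal BrainVision triplet; returns the .vhdr path.

    ``markers`` are (0-based sample, type, description) triples, e.g.
    ``(500, "Stimulus", "S  1")``.
    """
    directory = Path(directory)
    vhdr = directory / f"{basename}.vhdr"
    vmrk = directory / f"{basename}.vmrk"
    eeg = directory / f"{basename}.eeg"

    n_ch = data_uv.shape[0]
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={basename}.eeg",
        f"MarkerFile={basename}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(channel_names):
        lines.append(f"Ch{i + 1}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={basename}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20240101120000000000",
    ]
    for j, (sample, mtype, desc) in enumerate(markers):
        mlines.append(f"Mk{j + 2}={mtype},{desc},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    eeg.write_bytes(np.ascontiguousarray(data_uv.T, dtype="<f4").tobytes())
    return vhdr


def write_edf(path: Path, data_uv: np.ndarray, fs: float,
              channel_names: list[str]) -> Path:
    """Write a minimal single-record EDF file (int16, 0.1 µV resolution)."""
    path = Path(path)
    n_ch, n_samp = data_uv.shape

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2024 X X X", 80),
        pad("01.01.24", 8), pad("12.00.00", 8),
        pad(str(256 + 256 * n_ch), 8), pad("", 44), pad("1", 8),
        pad(f"{n_samp / fs:g}", 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("".join(pad(nm, 16).decode() for nm in channel_names), None),
        ("", 80), ("uV", 8), ("-3276.7", 8), ("3276.7", 8),
        ("-32767", 8), ("32767", 8), ("", 80), (str(n_samp), 8), ("", 32),
    ]
    sig = pad(fields[0][0], 16 * n_ch)
    for text, width in fields[1:]:
        sig += b"".join(pad(text, width) for _ in range(n_ch))
    digital = np.clip(np.round(data_uv / 0.1), -32767, 32767).astype("<i2")
    path.write_bytes(header + sig + digital.tobytes())
    return path


@pytest.fixture
def brainvision_raw(tmp_path, rng):
    """Synthetic 31-channel 500 Hz BrainVision triplet with 9 cue markers."""
    from mdeeg.simulate import MONTAGE_31

    fs = 500.0
    n_samples = 20000  # 40 s
    data = rng.standard_normal((31, n_samples)) * 10.0
    markers = []
    for i in range(9):
        code = f"S  {i % 3 + 1}"
        markers.append((1000 + i * 2000, "Stimulus", code))
    vhdr = write_brainvision(tmp_path, "session", data, fs, MONTAGE_31, markers)
    return vhdr, data, fs, markers


def synthetic_raw(rng, n_channels=4, fs=100.0, n_samples=5000, n_cues=6,
                  spacing=700, first=100) -> RawRecording:
    """In-memory continuous recording with evenly spaced cue events."""
    data = rng.standard_normal((n_channels, n_samples))
    events = [(first + i * spacing, f"cue{i % 2}") for i in range(n_cues)]
    return RawRecording(data, fs, [f"ch{i}" for i in range(n_channels)], events)
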