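"""Minimal EDF writer/reader for epoched data.

Each epoch is stored as one EDF data record (record duration = epoch length
in seconds), channels labeled from the montage.  Only the subset of the EDF
specification needed for round-tripping our epochs is implemented: 16-bit
samples, identical sampling rate across channels, one annotation-free
signal per channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(epochs: EpochSet, path: str | Path) -> None:
    """Write one EDF file; trials map 1:1 to data records."""
    data = epochs.data
    n_trials, n_ch, n_samp = data.shape
    duration = n_samp / epochs.fs

    phys_min = np.minimum(data.min(axis=(0, 2)), -1.0)
    phys_max = np.maximum(data.max(axis=(0, 2)), 1.0)
    # guard against degenerate ranges
    span = phys_max - phys_min
    phys_max = np.where(span < 1e-6, phys_min + 1.0, phys_max)

    header = b""
    header += _field("0", 8)
    header += _field("synthetic subject", 80)
    header += _field(f"epoched t0={epochs.t0_ms:g}ms fs={epochs.fs:g}Hz", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_trials), 8)
    header += _field(f"{duration:.6g}", 8)
    header += _field(str(n_ch), 4)
    header += b"".join(_field(c, 16) for c in epochs.channels)
    header += b"".join(_field("", 80) for _ in range(n_ch))          # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(_field(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))          # prefilter
    header += b"".join(_field(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    dig = np.round((data - phys_min[None, :, None]) / gain[None, :, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        dig.tofile(fh)  # record-major: (trial, channel, sample) contiguous


def read_edf(path: str | Path, trial_meta: pd.DataFrame | None = None,
             t0_ms: float | None = None) -> EpochSet:
    """Read an EDF written by :func:`write_edf` back into an :class:`EpochSet`."""
    raw = Path(path).read_bytes()

    def txt(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii").strip()

    n_records = int(txt(236, 8))
    duration = float(txt(244, 8))
    n_ch = int(txt(252, 4))
    off = 256
    labels = [txt(off + 16 * i, 16) for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch  # skip transducer + units
    phys_min = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    phys_max = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_min = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_max = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    n_samp = int(txt(off, 8))
    header_bytes = 256 * (1 + n_ch)

    dig = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    dig = dig.reshape(n_records, n_ch, n_samp).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (dig - dig_min[None, :, None]) * gain[None, :, None] + phys_min[None, :, None]

    fs = n_samp / duration
    recording = txt(88, 80)
    if t0_ms is None:
        t0_ms = 0.0
        for token in recording.split():
            if token.startswith("t0=") and token.endswith("ms"):
                t0_ms = float(token[3:-2])
    if trial_meta is None:
        trial_meta = pd.DataFrame(
            {"phase": [""] * n_records, "condition": [""] * n_records,
             "reinforced": [False] * n_records}
        )
    return EpochSet(data, fs, t0_ms, trial_meta, labels)
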