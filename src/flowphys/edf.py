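"""Minimal European Data Format (EDF) writer for the EEG export.

EDF stores an ASCII header followed by data records of 16-bit little-endian
integers, linearly mapped between per-signal physical and digital ranges.
This writer emits one-second data records and is intentionally small: it
covers exactly what the session export needs (equal-rate signals, one
continuous block).  Readback is tested against MNE's EDF reader.
"""

from __future__ import annotations

import datetime

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str,
    data: np.ndarray,
    sampling_rate: float,
    channel_names: list[str],
    physical_units: str = "uV",
    patient_id: str = "X",
) -> None:
    """Write ``data`` (n_samples x n_channels) as a 16-bit EDF file.

    The signal is truncated to a whole number of one-second records; the
    physical range is taken from the data (symmetric, padded 1%) so
    quantization error is at most range / 2^16 per sample.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(channel_names):
        raise ValueError("data must be (n_samples, n_channels)")
    rate = int(round(sampling_rate))
    if abs(rate - sampling_rate) > 1e-9 or rate <= 0:
        raise ValueError("EDF export requires an integral sampling rate")
    n_records = data.shape[0] // rate
    if n_records == 0:
        raise ValueError("less than one second of data")
    data = data[: n_records * rate]
    ns = len(channel_names)

    phys_max = float(np.max(np.abs(data))) * 1.01 + 1e-9
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale) + _DIG_MIN, _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("flowphys EEG export", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(name, 16) for name in channel_names),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_field(physical_units, 8) for _ in range(ns)),
            b"".join(_field(f"{phys_min:.8g}"[:8], 8) for _ in range(ns)),
            b"".join(_field(f"{phys_max:.8g}"[:8], 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(str(rate), 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[r * rate : (r + 1) * rate]  # (rate, ns)
            fh.write(block.T.tobytes())  # per-signal contiguous within record
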