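"""HR/SpO2 artifact repair and per-minute statistics; GSR minute summaries.

The PPG unit emits heart rate (BPM) and blood oxygen saturation (%) at 1 Hz.
Contact artifacts are repaired by neighbor averaging: each invalid sample is
replaced by the mean of the nearest valid value on its left and on its
right (a run of invalid samples shares the same two flanks; at a series
boundary the single available flank is used).  SpO2 validity is the fixed
[70, 100]% device range; HR validity combines per-subject bounds with a
robust z-score rule standing in for per-subject manual inspection.

Heart-rate variability is the time-domain sample SD of the HR series within
each 1-minute segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPO2_VALID_RANGE = (70.0, 100.0)
DEFAULT_HR_BOUNDS = (30.0, 220.0)


class UnusableSeriesError(ValueError):
    """No valid samples remain: the series cannot be repaired."""


@dataclass
class RepairLog:
    """Complete record of one series repair (replaces are reproducible)."""

    series_id: str
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    replacements: np.ndarray = field(default_factory=lambda: np.array([]))
    originals: np.ndarray = field(default_factory=lambda: np.array([]))
    rule: str = "range"

    @property
    def n_replaced(self) -> int:
        return len(self.indices)


def _neighbor_repair(
    series: np.ndarray, valid: np.ndarray, series_id: str, rule: str
) -> tuple[np.ndarray, RepairLog]:
    series = np.asarray(series, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise UnusableSeriesError(f"{series_id}: no valid samples")
    out = series.copy()
    invalid_idx = np.flatnonzero(~valid)
    if len(invalid_idx):
        valid_idx = np.flatnonzero(valid)
        # nearest valid flank on each side of every invalid sample
        pos = np.searchsorted(valid_idx, invalid_idx)
        left = np.where(pos > 0, valid_idx[np.maximum(pos - 1, 0)], -1)
        right = np.where(
            pos < len(valid_idx), valid_idx[np.minimum(pos, len(valid_idx) - 1)], -1
        )
        repl = np.empty(len(invalid_idx))
        for k, (l, r) in enumerate(zip(left, right)):
            if l >= 0 and r >= 0:
                repl[k] = 0.5 * (series[l] + series[r])
            elif l >= 0:
                repl[k] = series[l]
            else:
                repl[k] = series[r]
        out[invalid_idx] = repl
    log = RepairLog(
        series_id=series_id,
        indices=invalid_idx,
        replacements=out[invalid_idx].copy(),
        originals=series[invalid_idx].copy(),
        rule=rule,
    )
    return out, log


def repair_spo2(
    series: np.ndarray, series_id: str = "spo2"
) -> tuple[np.ndarray, RepairLog]:
    """Replace SpO2 samples outside the valid [70, 100]% range.

    Raises :class:`UnusableSeriesError` when no sample is valid.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = SPO2_VALID_RANGE
    valid = (series >= lo) & (series <= hi)
    return _neighbor_repair(series, valid, series_id, rule="range")


def repair_hr(
    series: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
    robust_k: float = 4.0,
    series_id: str = "hr",
) -> tuple[np.ndarray, RepairLog]:
    """Replace implausible HR samples by the SpO2 neighbor rule.

    A sample is invalid when outside ``bounds`` (per-subject overridable) or
    when its robust z-score |x - median| / (1.4826 * MAD) exceeds
    ``robust_k``.  A constant series has MAD 0; the z-rule is then inert.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy low < high")
    valid = (series >= lo) & (series <= hi)
    if valid.any() and robust_k > 0:
        med = np.median(series[valid])
        mad = np.median(np.abs(series[valid] - med))
        if mad > 0:
            z = np.abs(series - med) / (1.4826 * mad)
            valid &= z <= robust_k
    if not valid.any():
        raise UnusableSeriesError(f"{series_id}: no valid samples")
    return _neighbor_repair(series, valid, series_id, rule="subject_bounds")


def minute_stats(series: np.ndarray, rate: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute sample mean and SD (n-1 denominator).

    The series must span a whole number of minutes; a 480-s series yields 8
    (mean, SD) pairs, a 60-s baseline one pair.
    """
    series = np.asarray(series, dtype=float)
    per_min = int(round(60 * rate))
    if abs(per_min - 60 * rate) > 1e-9:
        raise ValueError(f"rate {rate} Hz gives a non-integral minute")
    if series.ndim != 1 or len(series) % per_min != 0:
        raise ValueError(
            f"series of {len(series)} samples is not a whole number of "
            f"minutes at {rate} Hz"
        )
    seg = series.reshape(-1, per_min)
    return seg.mean(axis=1), seg.std(axis=1, ddof=1)


def minute_usability(
    n_samples: int,
    rate: float,
    repaired_indices: np.ndarray,
    max_repaired_fraction: float = 0.5,
) -> np.ndarray:
    """Per-minute usability after repair.

    A minute is unusable when more than ``max_repaired_fraction`` of its
    samples had to be replaced — neighbor averaging cannot restore a mostly
    missing minute.
    """
    per_min = int(round(60 * rate))
    n_min = n_samples // per_min
    counts = np.zeros(n_min, dtype=int)
    mins = np.asarray(repaired_indices, dtype=int) // per_min
    for m in mins[mins < n_min]:
        counts[m] += 1
    return counts <= max_repaired_fraction * per_min


def flag_incomplete(usable_minutes: np.ndarray) -> bool:
    """True when the phase is complete (every minute usable).

    Subjects with an incomplete phase are excluded from cohort aggregation
    for that variable in that phase only.
    """
    return bool(np.all(usable_minutes))
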