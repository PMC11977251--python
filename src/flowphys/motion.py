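"""IMU activity quantification: Euclidean norm magnitude and per-minute SD.

Physical activity is summarized per device (headset, armband) as the sample
SD of the instantaneous magnitude of the 3-axis accelerometer and gyroscope
signals within 1-minute segments.  The norm is computed on raw samples and
gravity is not subtracted: a constant gravity offset shifts the mean of the
accelerometer magnitude but not its SD, which is the analyzed quantity.
"""

from __future__ import annotations

import numpy as np

from .autonomic import minute_stats


def vector_norm_series(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of a 3-axis signal."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("expected an (n_samples, 3) axis array")
    return np.sqrt(np.sum(xyz * xyz, axis=1))


def motion_minute_sd(
    block: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute SD of the accelerometer and gyroscope magnitude series.

    ``block`` is the 6-channel IMU block (acc xyz then gyro xyz); returns
    (acc_sd, gyro_sd) arrays with one value per minute.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 6:
        raise ValueError("expected an (n_samples, 6) IMU block")
    acc_norm = vector_norm_series(block[:, :3])
    gyr_norm = vector_norm_series(block[:, 3:])
    _, acc_sd = minute_stats(acc_norm, rate)
    _, gyr_sd = minute_stats(gyr_norm, rate)
    return acc_sd, gyr_sd
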