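"""Seedable synthetic cohorts with the statistical structure the analysis assumes.

Every generator emulates what the wearable devices actually emit:

* EEG: 1/f background plus narrowband random-phase oscillations in the
  delta/theta/alpha/beta bands, with stereotyped biphasic blink transients
  dominant on the Fp1/Fp2 channels.
* HR/SpO2 (PPG-derived, 1 Hz): AR(1) heart-rate noise around a condition
  mean with optional linear trend, quantized to 1 BPM; SpO2 near 97%
  quantized to 1%, with out-of-range dropout artifacts and implausible HR
  spikes.
* GSR (500 Hz): slowly drifting skin impedance quantized to 0.61 ohm.
* IMU (50 Hz, two devices): gravity-offset accelerometer plus sensor noise
  and sparse movement bursts correlated across axes and between the
  accelerometer and gyroscope.

The ``paper_like`` preset reproduces the qualitative condition ordering the
analysis is built to detect (boredom: largest theta/delta power increase and
most movement; flow: lowest HR variability and least movement; frustration:
highest heart rate).  The ``null`` preset makes all five phases identically
distributed, for type-I-error calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .session import (
    BLOCK_SECONDS,
    DEFAULT_CHANNELS,
    DEFAULT_RATES,
    DEFAULT_UNITS,
    PHASES,
    ModalityData,
    Session,
)

BANDS = ("delta", "theta", "alpha", "beta")

#: Relative blink amplitude per EEG channel (largest on Fp1/Fp2).
BLINK_TOPOGRAPHY = np.array([0.5, 1.0, 1.0, 0.5])

#: Fixed near-uniform scalp weights of the shared band oscillations over
#: AF7/Fp1/Fp2/AF8.  Frontal channels a few cm apart see almost the same
#: cortical sources (volume conduction), so oscillatory content is common
#: across channels up to small gains; only the 1/f background and sensor
#: noise are channel-specific.
BAND_TOPOGRAPHY = {
    "delta": np.array([1.06, 0.97, 1.02, 0.95]),
    "theta": np.array([0.96, 1.04, 0.98, 1.02]),
    "alpha": np.array([1.03, 0.95, 1.05, 0.97]),
    "beta": np.array([0.97, 1.03, 0.96, 1.04]),
}
#: Scalp weights of the shared aperiodic (1/f) background.
BACKGROUND_TOPOGRAPHY = np.array([1.02, 0.98, 1.01, 0.99])

GSR_QUANTUM = 0.61  # ohm, 12-bit device resolution


@dataclass
class PhaseEffect:
    """Generating parameters for one experimental phase.

    ``band_power`` values are power multipliers relative to the eyes-closed
    baseline oscillation power (amplitudes are scaled by their square root).
    """

    band_power: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BANDS}
    )
    hr_mean: float = 70.0  # BPM
    hr_sd: float = 3.0  # BPM
    hr_trend: float = 0.0  # BPM per minute
    spo2_mean: float = 97.0  # %
    gsr_level: float = 50000.0  # ohm
    gsr_drift: float = 0.0  # ohm per minute
    movement_rate: float = 0.2  # bursts per minute


@dataclass
class BurstParams:
    """Movement-burst shape shared by both IMUs."""

    acc_amplitude: float = 0.25  # g
    gyro_amplitude: float = 40.0  # dps
    min_duration: float = 0.5  # s
    max_duration: float = 2.0  # s


@dataclass
class SynthConfig:
    """Full description of a synthetic cohort."""

    n_subjects: int = 24
    seed: int = 0
    phases: dict[str, PhaseEffect] = field(default_factory=dict)
    # EEG background and oscillation base amplitudes (uV RMS, eyes-closed)
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 6.0, "theta": 5.0, "alpha": 6.0, "beta": 3.0}
    )
    one_over_f_exponent: float = 1.0
    background_rms: float = 3.0  # uV
    #: per-phase physiological state variability (iid across phases, so the
    #: null preset keeps conditions exchangeable)
    band_phase_jitter_sd: float = 0.15  # lognormal sigma, EEG band amplitude
    hr_phase_jitter_sd: float = 1.0  # BPM, additive on the phase HR mean
    hr_sd_phase_jitter_sd: float = 0.15  # lognormal sigma on the phase HR SD
    spo2_phase_jitter_sd: float = 0.5  # %, additive
    gsr_phase_jitter_sd: float = 1000.0  # ohm, additive on the phase level
    # artifact rates (per minute)
    blink_rate: float = 12.0
    hr_spike_rate: float = 1.0
    spo2_dropout_rate: float = 0.5
    burst: BurstParams = field(default_factory=BurstParams)
    gsr_noise_sd: float = 20.0  # ohm
    # marker slack around each analysis block, seconds (uniform integer)
    min_pad: int = 1
    max_pad: int = 5
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))

    def __post_init__(self):
        if not self.phases:
            self.phases = {p: PhaseEffect() for p in PHASES}
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, eff in self.phases.items():
            for b, m in eff.band_power.items():
                if m <= 0:
                    raise ValueError(f"{name}: band multiplier {b} must be > 0")
            if eff.movement_rate < 0:
                raise ValueError(f"{name}: movement_rate must be >= 0")
        for r in (self.blink_rate, self.hr_spike_rate, self.spo2_dropout_rate):
            if r < 0:
                raise ValueError("artifact rates must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def paper_like(n_subjects: int = 24, seed: int = 0, **overrides) -> SynthConfig:
    """Preset reproducing the qualitative condition ordering of the study.

    Boredom shows the largest theta (~6x) and delta (~5x) power increases
    over the eyes-closed baseline and the most movement; flow has the lowest
    heart-rate variability and the least movement; frustration the highest
    heart rate.  Eyes-open baseline has attenuated alpha (alpha blocking).
    """
    phases = {
        "baseline_closed": PhaseEffect(),
        "baseline_open": PhaseEffect(
            band_power={"delta": 1.0, "theta": 1.0, "alpha": 0.5, "beta": 1.0}
        ),
        "boredom": PhaseEffect(
            band_power={"delta": 5.0, "theta": 6.0, "alpha": 2.0, "beta": 2.0},
            hr_mean=72.0,
            hr_sd=3.5,
            movement_rate=4.0,
            gsr_level=49000.0,
            gsr_drift=-50.0,
        ),
        "flow": PhaseEffect(
            band_power={"delta": 2.5, "theta": 3.0, "alpha": 1.8, "beta": 2.2},
            hr_mean=70.5,
            hr_sd=2.0,
            movement_rate=0.5,
            spo2_mean=97.3,
            gsr_level=49600.0,
            gsr_drift=-20.0,
        ),
        "frustration": PhaseEffect(
            band_power={"delta": 0.8, "theta": 1.1, "alpha": 0.8, "beta": 2.0},
            hr_mean=74.0,
            hr_sd=4.5,
            movement_rate=3.0,
            gsr_level=48500.0,
            gsr_drift=-80.0,
        ),
    }
    return SynthConfig(n_subjects=n_subjects, seed=seed, phases=phases, **overrides)


def null_preset(n_subjects: int = 24, seed: int = 0, **overrides) -> SynthConfig:
    """All five phases identically distributed (no condition effect)."""
    return SynthConfig(
        n_subjects=n_subjects,
        seed=seed,
        phases={p: PhaseEffect() for p in PHASES},
        **overrides,
    )


PRESETS = {"paper_like": paper_like, "null": null_preset}


# ---------------------------------------------------------------------------
# Modality generators
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, rate: float, exponent: float, rng) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f^exponent above 0.5 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    weights = np.maximum(freqs, 0.5) ** (-exponent / 2.0)
    weights[0] = 0.0
    x = np.fft.irfft(spec * weights, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(n: int, rate: float, low: float, high: float, rng) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (random-phase oscillation)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_kernel(rate: float) -> np.ndarray:
    """Stereotyped biphasic blink transient, ~0.4 s."""
    t = np.arange(int(round(0.4 * rate))) / rate
    return np.exp(-(((t - 0.1) / 0.05) ** 2)) - 0.4 * np.exp(
        -(((t - 0.25) / 0.08) ** 2)
    )


#: Default band edges used by the generator (shared with the analysis side).
GEN_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}


def generate_eeg_block(
    duration: float,
    rate: float,
    band_amplitudes: dict[str, float],
    one_over_f_exponent: float = 1.0,
    background_rms: float = 3.0,
    blink_rate: float = 12.0,
    blink_amplitude: float = 120.0,
    sensor_noise_rms: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate a 4-channel EEG block (n_samples x 4, uV).

    Volume conduction makes closely spaced frontal electrodes see nearly the
    same cortical activity, so the 1/f background and the band-limited
    oscillations are shared sources projected through fixed near-uniform
    scalp weights; blink transients share the Fp1/Fp2-dominant topography.
    Only a small 1/f sensor-noise term (``sensor_noise_rms``) is
    channel-independent.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * rate))
    if abs(n - duration * rate) > 1e-6:
        raise ValueError("duration x rate must be integral")
    bg = background_rms * _one_over_f_noise(n, rate, one_over_f_exponent, rng)
    out = bg[:, None] * BACKGROUND_TOPOGRAPHY[None, :]
    if sensor_noise_rms > 0:
        for ch in range(4):
            out[:, ch] += sensor_noise_rms * _one_over_f_noise(
                n, rate, one_over_f_exponent, rng
            )
    for band, (low, high) in GEN_BAND_EDGES.items():
        amp = band_amplitudes.get(band, 0.0)
        if amp > 0:
            source = _narrowband_noise(n, rate, low, high, rng)
            out += amp * source[:, None] * BAND_TOPOGRAPHY[band][None, :]
    n_blinks = rng.poisson(blink_rate * duration / 60.0) if blink_rate > 0 else 0
    if n_blinks:
        kernel = _blink_kernel(rate)
        starts = rng.integers(0, max(1, n - len(kernel)), size=n_blinks)
        for s in np.sort(starts):
            amp = blink_amplitude * rng.lognormal(0.0, 0.2)
            seg = slice(s, s + len(kernel))
            out[seg] += amp * kernel[: n - s, None] * BLINK_TOPOGRAPHY[None, :]
    return np.round(out, 3)  # storage precision 0.001 uV


def generate_hr_spo2(
    duration: float,
    hr_mean: float,
    hr_sd: float,
    hr_trend: float = 0.0,
    spo2_mean: float = 97.0,
    spike_rate: float = 0.0,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    rate: float = 1.0,
    ar_coef: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate paired HR (BPM) and SpO2 (%) series at ``rate`` Hz.

    HR is mean + trend + AR(1) noise scaled to the target stationary SD,
    quantized to 1 BPM; spikes are implausible +60..+80 BPM excursions of
    1-3 samples.  SpO2 is quantized to 1%; dropouts fall below the valid
    70% floor for 1-5 samples.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * rate))
    t_min = np.arange(n) / (rate * 60.0)  # minutes
    if hr_sd > 0:
        innov_sd = hr_sd * math.sqrt(1.0 - ar_coef**2)
        e = rng.standard_normal(n) * innov_sd
        x0 = rng.standard_normal() * hr_sd  # stationary start
        ar, _ = sps.lfilter([1.0], [1.0, -ar_coef], e, zi=np.array([ar_coef * x0]))
    else:
        ar = np.zeros(n)
    hr = hr_mean + hr_trend * t_min + ar
    n_spikes = rng.poisson(spike_rate * duration / 60.0) if spike_rate > 0 else 0
    for _ in range(n_spikes):
        i = int(rng.integers(0, n))
        w = int(rng.integers(1, 4))
        hr[i : i + w] += rng.uniform(60.0, 80.0)
    hr = np.rint(hr).astype(float)

    spo2 = np.rint(spo2_mean + rng.standard_normal(n) * 0.5).astype(float)
    np.clip(spo2, 70.0, 100.0, out=spo2)
    n_drop = rng.poisson(dropout_rate * duration / 60.0) if dropout_rate > 0 else 0
    for _ in range(n_drop):
        i = int(rng.integers(0, n))
        w = int(rng.integers(1, 6))
        spo2[i : i + w] = float(rng.integers(0, 61))
    return hr, spo2


def generate_imu_block(
    duration: float,
    rate: float,
    movement_rate: float,
    burst_params: BurstParams | None = None,
    rng: np.random.Generator | None = None,
    acc_noise_sd: float = 0.005,
    gyro_noise_sd: float = 0.2,
) -> np.ndarray:
    """Generate a 6-channel IMU block (acc xyz in g, gyro xyz in dps).

    A stationary gravity vector (|acc| ~ 1 g) plus sensor noise, with
    Poisson-count movement bursts whose smooth envelope is shared between
    the accelerometer and gyroscope (correlated axes).
    """
    rng = np.random.default_rng() if rng is None else rng
    bp = burst_params or BurstParams()
    n = int(round(duration * rate))
    tilt = rng.standard_normal(3) * 0.05
    g_vec = np.array([0.0, 0.0, 1.0]) + tilt
    g_vec /= np.linalg.norm(g_vec)
    acc = g_vec[None, :] + rng.standard_normal((n, 3)) * acc_noise_sd
    gyr = rng.standard_normal((n, 3)) * gyro_noise_sd
    n_bursts = rng.poisson(movement_rate * duration / 60.0) if movement_rate > 0 else 0
    for _ in range(n_bursts):
        dur = rng.uniform(bp.min_duration, bp.max_duration)
        w = max(2, int(round(dur * rate)))
        i = int(rng.integers(0, max(1, n - w)))
        env = np.hanning(w)
        a_dir = rng.standard_normal(3)
        a_dir /= np.linalg.norm(a_dir)
        g_dir = rng.standard_normal(3)
        g_dir /= np.linalg.norm(g_dir)
        a_amp = abs(rng.normal(bp.acc_amplitude, bp.acc_amplitude * 0.3))
        g_amp = abs(rng.normal(bp.gyro_amplitude, bp.gyro_amplitude * 0.3))
        acc[i : i + w] += a_amp * env[:, None] * a_dir[None, :]
        gyr[i : i + w] += g_amp * env[:, None] * g_dir[None, :]
    out = np.empty((n, 6))
    out[:, :3] = np.round(acc, 5)  # ~16-bit accelerometer resolution
    out[:, 3:] = np.round(gyr, 3)
    return out


def generate_gsr_block(
    duration: float,
    rate: float,
    level: float,
    drift: float = 0.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 20.0,
) -> np.ndarray:
    """Generate a skin-impedance series (ohm): level + drift + slow noise.

    ``drift`` is in ohm per minute; output is quantized to the device's
    0.61-ohm resolution.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * rate))
    t_min = np.arange(n) / (rate * 60.0)
    x = level + drift * t_min
    if noise_sd > 0:
        # slow (~0.1 Hz) noise synthesized at 5 Hz and upsampled
        low_rate = 5.0
        m = int(math.ceil(duration * low_rate)) + 2
        slow = gaussian_filter1d(rng.standard_normal(m), sigma=2.0 * low_rate)
        sd = slow.std()
        if sd > 0:
            t_low = np.arange(m) / low_rate
            x = x + noise_sd * np.interp(np.arange(n) / rate, t_low, slow / sd)
    return np.round(np.rint(x / GSR_QUANTUM) * GSR_QUANTUM, 2)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig, subject_id: str, rng) -> Session:
    """Generate one subject: all five phases with random marker slack."""
    # subject-level traits, shared across phases (cancel in paired contrasts)
    hr_offset = rng.normal(0.0, 4.0)
    gsr_offset = rng.normal(0.0, 2000.0)
    band_scale = {b: rng.lognormal(0.0, 0.15) for b in BANDS}

    pieces: dict[str, list[np.ndarray]] = {m: [] for m in DEFAULT_RATES}
    markers: dict[str, tuple[float, float]] = {}
    t = 0.0
    for phase in PHASES:
        eff = config.phases[phase]
        pad = int(rng.integers(config.min_pad, config.max_pad + 1))
        interval = BLOCK_SECONDS[phase] + 2 * pad
        amps = {
            b: config.band_amplitudes[b]
            * band_scale[b]
            * rng.lognormal(0.0, config.band_phase_jitter_sd)
            * math.sqrt(eff.band_power.get(b, 1.0))
            for b in BANDS
        }
        pieces["eeg"].append(
            generate_eeg_block(
                interval,
                config.rates["eeg"],
                amps,
                config.one_over_f_exponent,
                config.background_rms,
                config.blink_rate,
                rng=rng,
            )
        )
        hr, spo2 = generate_hr_spo2(
            interval,
            eff.hr_mean + hr_offset + rng.normal(0.0, config.hr_phase_jitter_sd),
            eff.hr_sd * rng.lognormal(0.0, config.hr_sd_phase_jitter_sd),
            eff.hr_trend,
            eff.spo2_mean + rng.normal(0.0, config.spo2_phase_jitter_sd),
            config.hr_spike_rate,
            config.spo2_dropout_rate,
            rng=rng,
            rate=config.rates["hr"],
        )
        pieces["hr"].append(hr[:, None])
        pieces["spo2"].append(spo2[:, None])
        pieces["gsr"].append(
            generate_gsr_block(
                interval,
                config.rates["gsr"],
                eff.gsr_level
                + gsr_offset
                + rng.normal(0.0, config.gsr_phase_jitter_sd),
                eff.gsr_drift,
                rng=rng,
                noise_sd=config.gsr_noise_sd,
            )[:, None]
        )
        for device in ("imu_headset", "imu_armband"):
            pieces[device].append(
                generate_imu_block(
                    interval,
                    config.rates[device],
                    eff.movement_rate,
                    config.burst,
                    rng=rng,
                )
            )
        markers[phase] = (t, t + interval)
        t += interval

    modalities = {
        m: ModalityData(
            modality=m,
            channels=DEFAULT_CHANNELS[m],
            sampling_rate=config.rates[m],
            units=DEFAULT_UNITS[m],
            data=np.concatenate(pieces[m], axis=0),
        )
        for m in DEFAULT_RATES
    }
    return Session(
        subject_id=subject_id,
        modalities=modalities,
        phase_markers=markers,
        metadata={"synthetic": True},
    )


def generate_cohort(config: SynthConfig) -> list[Session]:
    """Generate ``config.n_subjects`` sessions, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    return [
        generate_session(config, f"S{i + 1:02d}", rng)
        for i in range(config.n_subjects)
    ]
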