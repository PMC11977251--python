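"""EEG pathway: band-pass filtering, bad-channel handling, ICA artifact
removal, 1-minute segmentation, Fourier band power and the log transform
used by the statistics.

The processing order mirrors the acquisition-to-statistics chain: a
zero-phase 0.5-30 Hz second-order Butterworth band-pass, removal of bad
channels, blink rejection by independent component analysis, partitioning
into 1-minute segments, and summation of the one-sided periodogram over the
delta (0.5-4), theta (4-7), alpha (8-12) and beta (13-30 Hz) bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import kurtosis, pearsonr
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .session import EEG_CHANNELS, PhaseSet

#: Relative blink amplitude template over the AF7/Fp1/Fp2/AF8 montage.
BLINK_TEMPLATE = {"AF7": 0.5, "Fp1": 1.0, "Fp2": 1.0, "AF8": 0.5}


@dataclass(frozen=True)
class Band:
    low: float
    high: float
    inclusive_upper: bool = False


@dataclass
class BandScheme:
    """Ordered band edges; the beta band closes at its 30 Hz upper edge.

    Edges at 7-8 and 12-13 Hz leave gaps that are intentionally unassigned,
    so the four band powers need not sum to the total spectral power.
    """

    bands: dict[str, Band] = field(
        default_factory=lambda: {
            "delta": Band(0.5, 4.0),
            "theta": Band(4.0, 7.0),
            "alpha": Band(8.0, 12.0),
            "beta": Band(13.0, 30.0, inclusive_upper=True),
        }
    )

    def __post_init__(self):
        for name, b in self.bands.items():
            if not b.low < b.high:
                raise ValueError(f"band {name}: low must be < high")

    @property
    def names(self) -> list[str]:
        return list(self.bands)


DEFAULT_SCHEME = BandScheme()


@dataclass
class ChannelQuality:
    """Good/bad status per channel with the reason and its source."""

    status: dict[str, str]  # channel -> "good" | "bad"
    reasons: dict[str, str] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)  # "auto" | "override"

    @property
    def good(self) -> list[str]:
        return [c for c, s in self.status.items() if s == "good"]

    @property
    def bad(self) -> list[str]:
        return [c for c, s in self.status.items() if s == "bad"]


class AllChannelsBadError(ValueError):
    """All four EEG channels rejected: subject cannot be analyzed."""


def bandpass_filter(
    x: np.ndarray,
    rate: float,
    low: float = 0.5,
    high: float = 30.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The filter is designed at the requested order; the forward-backward pass
    squares its magnitude response and cancels the phase.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= rate / 2:
        raise ValueError(f"high edge {high} Hz >= Nyquist {rate / 2} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def detect_bad_channels(
    eeg_block: np.ndarray,
    channels: tuple[str, ...] = EEG_CHANNELS,
    flat_sd: float = 0.1,
    extreme_k: float = 10.0,
    overrides: list[str] | None = None,
) -> ChannelQuality:
    """Flag flat or extreme channels; a manual override list wins over auto.

    A channel is flat if its SD falls below ``flat_sd`` (uV) and extreme if
    its SD exceeds ``extreme_k`` times the median channel SD.
    """
    eeg_block = np.asarray(eeg_block, dtype=float)
    sds = eeg_block.std(axis=0, ddof=1)
    med = float(np.median(sds))
    status, reasons, source = {}, {}, {}
    for i, ch in enumerate(channels):
        if overrides and ch in overrides:
            status[ch], reasons[ch], source[ch] = "bad", "manual override", "override"
        elif sds[i] < flat_sd:
            status[ch] = "bad"
            reasons[ch] = f"flat (SD {sds[i]:.3g} uV < {flat_sd})"
            source[ch] = "auto"
        elif med > 0 and sds[i] > extreme_k * med:
            status[ch] = "bad"
            reasons[ch] = f"extreme (SD {sds[i]:.3g} uV > {extreme_k}x median)"
            source[ch] = "auto"
        else:
            status[ch], reasons[ch], source[ch] = "good", "", "auto"
    quality = ChannelQuality(status, reasons, source)
    if not quality.good:
        raise AllChannelsBadError("all EEG channels flagged bad")
    return quality


def remove_artifacts_ica(
    eeg_block: np.ndarray,
    channels: tuple[str, ...],
    seed: int = 0,
    corr_threshold: float = 0.8,
    kurtosis_gate: float = 2.0,
    kurtosis_threshold: float = 8.0,
    max_reject: int = 1,
) -> tuple[np.ndarray, dict]:
    """Decompose into as many components as channels; reject the blink one.

    A component qualifies as a blink if its mixing pattern correlates with
    the Fp-dominant topography (|r| > ``corr_threshold``) while being
    heavy-tailed (excess kurtosis > ``kurtosis_gate``), or if it is extremely
    heavy-tailed on its own (excess kurtosis > ``kurtosis_threshold``).
    Among qualifying components the most heavy-tailed is removed; at most
    ``max_reject`` components are rejected.  The pattern test alone is not
    trusted: with four channels a Gaussian background yields arbitrary
    mixing directions, and four-point correlations exceed 0.8 by chance.

    Returns the reconstructed block and an info dict (rejected component
    index or None, per-component kurtosis and pattern correlation,
    ``converged`` flag; on decomposition failure the input passes through
    with ``converged=False``).
    """
    X = np.asarray(eeg_block, dtype=float)
    n_comp = X.shape[1]
    if n_comp < 2:
        return X.copy(), {"rejected": None, "converged": True, "note": "one channel"}
    template = np.array([BLINK_TEMPLATE[c] for c in channels])
    info: dict = {"rejected": None, "converged": False}
    S = None
    for attempt in range(3):
        # Full convergence is not required: any rotation within a Gaussian
        # background subspace is unidentifiable and FastICA may iterate
        # there forever, but the heavy-tailed blink axis locks in early and
        # the reconstruction S @ A.T inverts exactly either way.
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_comp,
                    random_state=seed + attempt,
                    whiten="unit-variance",
                    max_iter=200,
                )
                S = ica.fit_transform(X)
            info["converged"] = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            if np.all(np.isfinite(S)):
                break
            S = None
        except ValueError:
            S = None
    if S is None:
        info["note"] = "ICA decomposition failed; block passed through"
        return X.copy(), info
    A = ica.mixing_  # (n_channels, n_components)
    kurts = kurtosis(S, axis=0, fisher=True)
    corrs = np.array(
        [abs(pearsonr(A[:, j], template)[0]) for j in range(S.shape[1])]
    )
    info["kurtosis"] = kurts
    info["pattern_corr"] = corrs
    qualify = ((corrs > corr_threshold) & (kurts > kurtosis_gate)) | (
        kurts > kurtosis_threshold
    )
    if qualify.any():
        order = np.argsort(kurts)[::-1]
        reject = [j for j in order if qualify[j]][:max_reject]
        S_clean = S.copy()
        S_clean[:, reject] = 0.0
        info["rejected"] = int(reject[0])
        return S_clean @ A.T + ica.mean_, info
    return X.copy(), info


def segment_minutes(block: np.ndarray, rate: float) -> list[np.ndarray]:
    """Split a block into consecutive non-overlapping 60-s segments."""
    block = np.asarray(block)
    per_min = int(round(60 * rate))
    if block.shape[0] % per_min != 0:
        raise ValueError(
            f"block of {block.shape[0]} samples is not a whole number of "
            f"minutes at {rate} Hz"
        )
    n_min = block.shape[0] // per_min
    return [block[i * per_min : (i + 1) * per_min] for i in range(n_min)]


def periodogram_power(segment: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed segment.

    Scaled so the bin values sum to the signal variance (Parseval); a unit
    amplitude sinusoid at a bin frequency contributes 0.5 (its power).
    """
    x = np.asarray(segment, dtype=float)
    x = x - x.mean()
    n = len(x)
    X = np.fft.rfft(x)
    p = (np.abs(X) ** 2) / (n * n)
    if n % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    return freqs, p


def band_power(
    segment: np.ndarray, rate: float, scheme: BandScheme = DEFAULT_SCHEME
) -> dict[str, float]:
    """Sum the one-sided periodogram over each band's frequency bins.

    Bins satisfy ``low <= f < high`` (half-open); a band marked
    ``inclusive_upper`` (beta) also takes its upper-edge bin.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 2 * rate:
        raise ValueError("segment must be at least 2 s long")
    nyquist = rate / 2.0
    for name, b in scheme.bands.items():
        if b.low < 0 or b.high > nyquist:
            raise ValueError(f"band {name} outside [0, Nyquist]")
    freqs, p = periodogram_power(segment, rate)
    out = {}
    for name, b in scheme.bands.items():
        if b.inclusive_upper:
            mask = (freqs >= b.low - 1e-12) & (freqs <= b.high + 1e-12)
        else:
            mask = (freqs >= b.low - 1e-12) & (freqs < b.high - 1e-12)
        out[name] = float(p[mask].sum())
    return out


def log_transform_power(power: float) -> float:
    """Natural log of a band power; downstream statistics use log ratios."""
    if power <= 0:
        raise ValueError("power must be positive for the log transform")
    return float(np.log(power))


def eeg_minute_powers(
    phase_set: PhaseSet,
    quality: ChannelQuality,
    scheme: BandScheme = DEFAULT_SCHEME,
    filter_low: float = 0.5,
    filter_high: float = 30.0,
    filter_order: int = 2,
    ica_seed: int = 0,
    ica_params: dict | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Full EEG chain for one subject: filter, drop bad channels, ICA,
    segment, band power.

    Returns a tidy frame (phase, channel, band, minute, power) containing
    only good channels — minute is 1-based, baselines have a single
    minute — plus the per-phase ICA info records.
    """
    rate = phase_set.rates["eeg"]
    channels = phase_set.channels["eeg"]
    good_idx = [i for i, c in enumerate(channels) if c in quality.good]
    good_names = tuple(channels[i] for i in good_idx)
    rows = []
    ica_infos = []
    for phase in sorted({p for (p, m) in phase_set.blocks if m == "eeg"}):
        block = phase_set.block(phase, "eeg")
        filtered = bandpass_filter(block, rate, filter_low, filter_high, filter_order)
        good = filtered[:, good_idx]
        if len(good_idx) >= 2:
            clean, info = remove_artifacts_ica(
                good, good_names, seed=ica_seed, **(ica_params or {})
            )
        else:
            clean, info = good, {"rejected": None, "converged": True}
        info = dict(info, phase=phase)
        ica_infos.append(info)
        for minute, segment in enumerate(segment_minutes(clean, rate), start=1):
            for ci, ch in enumerate(good_names):
                powers = band_power(segment[:, ci], rate, scheme)
                for band, p in powers.items():
                    rows.append(
                        {
                            "phase": phase,
                            "channel": ch,
                            "band": band,
                            "minute": minute,
                            "power": p,
                        }
                    )
    return pd.DataFrame(rows), ica_infos
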