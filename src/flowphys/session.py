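"""Session data model, on-disk session format and centered phase partitioning.

A *session* is one subject's multimodal recording: four-channel prefrontal
EEG, two six-axis IMUs (headset and armband), skin-impedance GSR, and
PPG-derived heart rate and SpO2, together with markers delimiting the five
experimental phases (eyes-open baseline, eyes-closed baseline, and the
boredom / flow / frustration game conditions).

On disk a session is a directory holding a JSON manifest plus one
tab-delimited text file per modality (one column per channel, one row per
sample).  The format is deliberately human-inspectable and language-neutral.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

#: Phase names in canonical order.
PHASES = ("baseline_open", "baseline_closed", "boredom", "flow", "frustration")
#: The three game conditions.
CONDITIONS = ("boredom", "flow", "frustration")
#: The two resting baselines.
BASELINES = ("baseline_open", "baseline_closed")

#: Analysis block length per phase, seconds.
BLOCK_SECONDS = {
    "baseline_open": 60,
    "baseline_closed": 60,
    "boredom": 480,
    "flow": 480,
    "frustration": 480,
}

#: Fixed EEG montage of the headset (10-20 positions).
EEG_CHANNELS = ("AF7", "Fp1", "Fp2", "AF8")
IMU_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

MODALITIES = ("eeg", "imu_headset", "imu_armband", "gsr", "hr", "spo2")

#: Default sampling rates (Hz) and physical units per modality.
DEFAULT_RATES = {
    "eeg": 250.0,
    "imu_headset": 50.0,
    "imu_armband": 50.0,
    "gsr": 500.0,
    "hr": 1.0,
    "spo2": 1.0,
}
DEFAULT_UNITS = {
    "eeg": "uV",
    "imu_headset": "g/dps",
    "imu_armband": "g/dps",
    "gsr": "ohm",
    "hr": "BPM",
    "spo2": "%",
}
DEFAULT_CHANNELS = {
    "eeg": EEG_CHANNELS,
    "imu_headset": IMU_CHANNELS,
    "imu_armband": IMU_CHANNELS,
    "gsr": ("gsr",),
    "hr": ("hr",),
    "spo2": ("spo2",),
}


class SessionFormatError(ValueError):
    """Raised when a session directory does not match the manifest contract."""


class SessionValidationError(ValueError):
    """Raised when a session's markers or channels violate an invariant."""


@dataclass(frozen=True)
class ChannelSpec:
    """Metadata for one recorded channel."""

    name: str
    modality: str
    sampling_rate: float
    units: str

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise SessionValidationError(
                f"channel {self.name}: sampling_rate must be positive"
            )
        if self.modality not in MODALITIES:
            raise SessionValidationError(f"unknown modality {self.modality!r}")


@dataclass
class ModalityData:
    """All channels of one modality: shared rate, 2-D sample array."""

    modality: str
    channels: tuple[str, ...]
    sampling_rate: float
    units: str
    data: np.ndarray  # shape (n_samples, n_channels)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] != len(self.channels):
            raise SessionValidationError(
                f"{self.modality}: {self.data.shape[1]} columns for "
                f"{len(self.channels)} declared channels"
            )

    @property
    def duration(self) -> float:
        return self.data.shape[0] / self.sampling_rate

    def specs(self) -> list[ChannelSpec]:
        return [
            ChannelSpec(name, self.modality, self.sampling_rate, self.units)
            for name in self.channels
        ]


@dataclass
class Session:
    """One subject's raw multimodal recording with phase markers.

    Phase markers are half-open intervals ``[start, end)`` in seconds from
    recording start, shared across modalities.
    """

    subject_id: str
    modalities: dict[str, ModalityData]
    phase_markers: dict[str, tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check marker/channel invariants; raise SessionValidationError."""
        missing = [p for p in PHASES if p not in self.phase_markers]
        if missing:
            raise SessionValidationError(
                f"subject {self.subject_id}: missing phase markers: "
                + ", ".join(missing)
            )
        if "eeg" in self.modalities:
            if tuple(self.modalities["eeg"].channels) != EEG_CHANNELS:
                raise SessionValidationError(
                    f"subject {self.subject_id}: EEG montage must be "
                    f"{EEG_CHANNELS}, got {self.modalities['eeg'].channels}"
                )
        durations = {m: md.duration for m, md in self.modalities.items()}
        rec_end = min(durations.values()) if durations else 0.0
        for phase, (start, end) in self.phase_markers.items():
            if start < 0 or end <= start:
                raise SessionValidationError(
                    f"subject {self.subject_id}: phase {phase!r} has invalid "
                    f"interval [{start}, {end})"
                )
            # allow sub-sample slack of the slowest modality
            slack = max(1.0 / md.sampling_rate for md in self.modalities.values())
            if end > rec_end + slack:
                raise SessionValidationError(
                    f"subject {self.subject_id}: phase {phase!r} ends at "
                    f"{end} s, beyond recording end {rec_end:.3f} s"
                )
        intervals = sorted(self.phase_markers.values())
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise SessionValidationError(
                    f"subject {self.subject_id}: overlapping phase markers "
                    f"[{s0},{e0}) and [{s1},{e1})"
                )


@dataclass
class PhaseSet:
    """Fixed-length per-phase signal blocks (60 s baselines, 480 s conditions).

    ``blocks[(phase, modality)]`` is a 2-D array of exactly
    ``BLOCK_SECONDS[phase] * rate`` samples, centered in the marker interval.
    """

    subject_id: str
    blocks: dict[tuple[str, str], np.ndarray]
    rates: dict[str, float]
    channels: dict[str, tuple[str, ...]]
    units: dict[str, str]

    def block(self, phase: str, modality: str) -> np.ndarray:
        return self.blocks[(phase, modality)]


def partition_phases(session: Session) -> PhaseSet:
    """Extract centered fixed-length blocks for every phase and modality.

    For a marker interval of length ``L`` and target length ``T`` the block
    starts ``(L - T) / 2`` after the marker start; sample offsets are rounded
    toward zero (floored) per modality, so the same amount of unused data
    precedes and succeeds the analysis block up to one sample period.
    """
    session.validate()
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for phase in PHASES:
        start, end = session.phase_markers[phase]
        target = BLOCK_SECONDS[phase]
        length = end - start
        if length < target - 1e-9:
            raise SessionValidationError(
                f"subject {session.subject_id}: phase {phase!r} shorter than "
                f"target ({length:.3f} s < {target} s)"
            )
        offset_s = (length - target) / 2.0
        for modality, md in session.modalities.items():
            rate = md.sampling_rate
            start_sample = int(math.floor(start * rate + 1e-9)) + int(
                math.floor(offset_s * rate + 1e-9)
            )
            count = target * rate
            n = int(round(count))
            if abs(count - n) > 1e-6:
                raise SessionValidationError(
                    f"{modality}: block of {target} s is not integral at "
                    f"{rate} Hz"
                )
            blocks[(phase, modality)] = md.data[start_sample : start_sample + n]
    return PhaseSet(
        subject_id=session.subject_id,
        blocks=blocks,
        rates={m: md.sampling_rate for m, md in session.modalities.items()},
        channels={m: tuple(md.channels) for m, md in session.modalities.items()},
        units={m: md.units for m, md in session.modalities.items()},
    )


# ---------------------------------------------------------------------------
# On-disk format: manifest.json + one TSV per modality
# ---------------------------------------------------------------------------

def write_session(session: Session, path: str, edf_export: bool = False) -> None:
    """Write a session directory (manifest + per-modality TSVs).

    ``read_session`` inverts this exactly: the TSVs carry shortest
    round-trip float representations.  With ``edf_export`` the EEG channels
    are additionally emitted as ``eeg.edf`` (16-bit European Data Format).
    """
    session.validate()
    os.makedirs(path, exist_ok=True)
    manifest = {
        "subject_id": session.subject_id,
        "phase_markers": {p: list(session.phase_markers[p]) for p in PHASES},
        "modalities": {},
        "metadata": session.metadata,
    }
    for modality, md in session.modalities.items():
        fname = f"{modality}.tsv"
        manifest["modalities"][modality] = {
            "file": fname,
            "sampling_rate": md.sampling_rate,
            "units": md.units,
            "channels": list(md.channels),
            "n_samples": int(md.data.shape[0]),
        }
        _write_tsv(os.path.join(path, fname), md.channels, md.data)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if edf_export and "eeg" in session.modalities:
        from .edf import write_edf

        md = session.modalities["eeg"]
        write_edf(
            os.path.join(path, "eeg.edf"),
            md.data,
            md.sampling_rate,
            list(md.channels),
            physical_units=md.units,
            patient_id=session.subject_id,
        )


def read_session(path: str) -> Session:
    """Read a session directory written by :func:`write_session`."""
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.isfile(manifest_path):
        raise SessionFormatError(f"no manifest.json in {path}")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        manifest["subject_id"], manifest["modalities"], manifest["phase_markers"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise SessionFormatError(f"malformed manifest in {path}: {exc}") from exc
    modalities: dict[str, ModalityData] = {}
    for modality, info in manifest["modalities"].items():
        fpath = os.path.join(path, info["file"])
        if not os.path.isfile(fpath):
            raise SessionFormatError(
                f"manifest declares {info['file']} but the file is missing"
            )
        channels, data = _read_tsv(fpath)
        if channels != tuple(info["channels"]):
            raise SessionFormatError(
                f"{info['file']}: header {channels} does not match manifest "
                f"channels {info['channels']}"
            )
        if data.shape[0] != info["n_samples"]:
            raise SessionFormatError(
                f"{info['file']}: {data.shape[0]} samples, manifest declares "
                f"{info['n_samples']}"
            )
        modalities[modality] = ModalityData(
            modality=modality,
            channels=channels,
            sampling_rate=float(info["sampling_rate"]),
            units=info["units"],
            data=data,
        )
    session = Session(
        subject_id=manifest["subject_id"],
        modalities=modalities,
        phase_markers={
            p: (float(v[0]), float(v[1]))
            for p, v in manifest["phase_markers"].items()
        },
        metadata=manifest.get("metadata", {}),
    )
    session.validate()
    return session


def _write_tsv(path: str, channels: tuple[str, ...], data: np.ndarray) -> None:
    # repr() floats give shortest exact round-trip strings; synthetic signals
    # are quantized to device resolution, keeping the files compact.
    with open(path, "w") as fh:
        fh.write("\t".join(channels) + "\n")
        for row in data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _read_tsv(path: str) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size == 0:
        data = data.reshape(0, len(header))
    return header, data
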