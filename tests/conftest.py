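import numpy as np
import pytest

import flowphys as fp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(modalities_spec, markers, subject_id="T01"):
    """Build a Session from {modality: (rate, n_channels, duration_s)}."""
    modalities = {}
    for modality, (rate, n_ch, dur) in modalities_spec.items():
        n = int(round(rate * dur))
        channels = fp.session.DEFAULT_CHANNELS.get(modality)
        if channels is None or len(channels) != n_ch:
            channels = tuple(f"ch{i}" for i in range(n_ch))
        # ramp per channel so sample indices are recoverable from values
        data = np.tile(np.arange(n, dtype=float)[:, None], (1, n_ch))
        modalities[modality] = fp.ModalityData(
            modality=modality,
            channels=channels,
            sampling_rate=rate,
            units=fp.session.DEFAULT_UNITS.get(modality, "au"),
            data=data,
        )
    return fp.Session(
        subject_id=subject_id, modalities=modalities, phase_markers=dict(markers)
    )


FULL_MARKERS = {
    "baseline_open": (0.0, 70.0),
    "baseline_closed": (70.0, 140.0),
    "boredom": (140.0, 640.0),
    "flow": (640.0, 1140.0),
    "frustration": (1140.0, 1640.0),
}


@pytest.fixture
def hr_session():
    """HR/SpO2-only session with slack around every phase (1 Hz, light)."""
    return make_session(
        {"hr": (1.0, 1, 1640.0), "spo2": (1.0, 1, 1640.0)}, FULL_MARKERS
    )


@pytest.fixture(scope="session")
def synth_subject():
    """One full paper_like synthetic subject, shared across tests."""
    config = fp.paper_like(n_subjects=1, seed=777)
    return fp.generate_cohort(config)[0]


@pytest.fixture(scope="session")
def synth_phase_set(synth_subject):
    return fp.partition_phases(synth_subject)
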