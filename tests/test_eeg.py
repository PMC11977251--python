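"""EEG chain: filter response, bad channels, ICA blink rejection,
segmentation and Fourier band power against a brute-force DFT oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowphys as fp
from flowphys.eeg import DEFAULT_SCHEME

RATE = 250.0


def brute_force_band_power(segment, rate, scheme=DEFAULT_SCHEME):
    """Independent oracle: explicit DFT sums over the band's bins."""
    x = np.asarray(segment, dtype=float)
    x = x - x.mean()
    n = len(x)
    t = np.arange(n)
    out = {}
    for name, band in scheme.bands.items():
        k_lo = int(np.ceil(band.low * n / rate - 1e-9))
        if band.inclusive_upper:
            k_hi = int(np.floor(band.high * n / rate + 1e-9))
        else:
            k_hi = int(np.ceil(band.high * n / rate - 1e-9)) - 1
        total = 0.0
        for k in range(k_lo, k_hi + 1):
            c = np.exp(-2j * np.pi * k * t / n)
            coef = np.dot(x, c)
            scale = 2.0 if 0 < k < n / 2 else 1.0
            total += scale * (abs(coef) ** 2) / (n * n)
        out[name] = total
    return out


class TestBandpassFilter:
    def _tone(self, freq, dur=10.0):
        t = np.arange(int(dur * RATE)) / RATE
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved(self):
        y = fp.bandpass_filter(self._tone(10.0), RATE)
        mid = y[len(y) // 4 : -len(y) // 4]  # avoid edge transients
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_tone_attenuated(self):
        y = fp.bandpass_filter(self._tone(60.0), RATE)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert np.abs(mid).max() < 0.1  # >= 90% amplitude attenuation

    def test_zero_in_zero_out(self):
        assert np.allclose(fp.bandpass_filter(np.zeros(1000), RATE), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fp.bandpass_filter(np.ones(100), RATE, low=0.5, high=130.0)


class TestBadChannels:
    def _block(self, rng):
        return rng.standard_normal((5000, 4)) * 10

    def test_flat_channel_flagged(self, rng):
        block = self._block(rng)
        block[:, 2] = 0.0
        q = fp.detect_bad_channels(block)
        assert q.status["Fp2"] == "bad" and "flat" in q.reasons["Fp2"]

    def test_extreme_channel_flagged(self, rng):
        block = self._block(rng)
        block[:, 0] *= 50
        q = fp.detect_bad_channels(block)
        assert q.status["AF7"] == "bad" and "extreme" in q.reasons["AF7"]

    def test_clean_synthetic_block_all_good(self, synth_phase_set):
        block = fp.bandpass_filter(synth_phase_set.block("flow", "eeg"), RATE)
        q = fp.detect_bad_channels(block)
        assert q.good == list(fp.EEG_CHANNELS)

    def test_manual_override_wins(self, rng):
        q = fp.detect_bad_channels(self._block(rng), overrides=["AF8"])
        assert q.status["AF8"] == "bad" and q.source["AF8"] == "override"

    def test_all_bad_raises(self):
        with pytest.raises(fp.eeg.AllChannelsBadError):
            fp.detect_bad_channels(np.zeros((5000, 4)))


class TestIca:
    AMPS = {"delta": 6.0, "theta": 5.0, "alpha": 6.0, "beta": 3.0}

    def _paired_blocks(self, seed=11, dur=120):
        """Same EEG background with and without blinks (shared seed)."""
        with_b = fp.generate_eeg_block(
            dur, RATE, dict(self.AMPS), blink_rate=12,
            rng=np.random.default_rng(seed),
        )
        without = fp.generate_eeg_block(
            dur, RATE, dict(self.AMPS), blink_rate=0,
            rng=np.random.default_rng(seed),
        )
        return with_b, without

    def test_blink_removal_restores_kurtosis_and_band_power(self):
        from scipy.stats import kurtosis

        with_b, without = self._paired_blocks()
        clean, info = fp.remove_artifacts_ica(with_b, fp.EEG_CHANNELS, seed=0)
        assert info["rejected"] is not None
        assert kurtosis(clean[:, 1]) < kurtosis(with_b[:, 1]) / 2
        for ch in range(4):
            p_clean = fp.band_power(clean[:, ch], RATE)
            p_true = fp.band_power(without[:, ch], RATE)
            for band in ("alpha", "beta"):
                assert abs(p_clean[band] - p_true[band]) / p_true[band] < 0.15

    def test_blink_free_block_mostly_untouched(self):
        _, without = self._paired_blocks()
        clean, info = fp.remove_artifacts_ica(without, fp.EEG_CHANNELS, seed=0)
        if info["rejected"] is None:
            assert np.allclose(clean, without)
        else:
            err = np.linalg.norm(clean - without) / np.linalg.norm(without)
            assert err < 0.05

    def test_deterministic_under_fixed_seed(self):
        with_b, _ = self._paired_blocks()
        a, _ = fp.remove_artifacts_ica(with_b, fp.EEG_CHANNELS, seed=3)
        b, _ = fp.remove_artifacts_ica(with_b, fp.EEG_CHANNELS, seed=3)
        assert np.array_equal(a, b)


class TestSegmentation:
    def test_condition_block_gives_eight_minutes(self):
        block = np.zeros((480 * 250, 4))
        segs = fp.segment_minutes(block, RATE)
        assert len(segs) == 8 and all(s.shape == (15000, 4) for s in segs)

    def test_baseline_gives_one_segment(self):
        assert len(fp.segment_minutes(np.zeros(60 * 250), RATE)) == 1

    def test_concatenation_recovers_input(self, rng):
        block = rng.standard_normal(120 * 250)
        assert np.array_equal(
            np.concatenate(fp.segment_minutes(block, RATE)), block
        )

    def test_partial_minute_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            fp.segment_minutes(np.zeros(250 * 90), RATE)


class TestBandPower:
    def test_pure_alpha_tone_concentrates_in_alpha(self):
        t = np.arange(60 * 250) / RATE
        tone = np.sin(2 * np.pi * 10.0 * t)
        p = fp.band_power(tone, RATE)
        total = sum(p.values())
        assert p["alpha"] / total > 0.99
        assert abs(p["alpha"] - 0.5) < 1e-6  # unit amplitude -> power 1/2

    def test_white_noise_band_power_tracks_bandwidth(self, rng):
        ratios = []
        for _ in range(40):
            p = fp.band_power(rng.standard_normal(60 * 250), RATE)
            ratios.append(p["beta"] / p["delta"])
        expected = (30 - 13) / (4 - 0.5)
        assert abs(np.mean(ratios) - expected) / expected < 0.10

    def test_zero_segment_zero_power(self):
        p = fp.band_power(np.zeros(60 * 250), RATE)
        assert all(v == 0.0 for v in p.values())

    def test_band_outside_nyquist_rejected(self):
        scheme = fp.BandScheme(bands={"hf": fp.Band(100.0, 140.0)})
        with pytest.raises(ValueError, match="Nyquist"):
            fp.band_power(np.zeros(1000), RATE, scheme)

    def test_matches_brute_force_dft_oracle(self, rng):
        for _ in range(3):
            seg = rng.standard_normal(10 * 250)
            fast = fp.band_power(seg, RATE)
            slow = brute_force_band_power(seg, RATE)
            for band in fast:
                assert fast[band] == pytest.approx(slow[band], rel=1e-9)

    def test_band_sum_bounded_by_total_power(self, rng):
        seg = rng.standard_normal(60 * 250)
        p = fp.band_power(seg, RATE)
        _, per = fp.periodogram_power(seg, RATE)
        assert sum(p.values()) <= per[1:].sum() + 1e-12

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_equivariance(self, c):
        rng = np.random.default_rng(99)
        seg = rng.standard_normal(4 * 250)
        base = fp.band_power(fp.bandpass_filter(seg, RATE), RATE)
        scaled = fp.band_power(fp.bandpass_filter(c * seg, RATE), RATE)
        for band in base:
            assert scaled[band] == pytest.approx(c * c * base[band], rel=1e-9)


class TestLogTransform:
    def test_values_and_monotonicity(self):
        assert fp.log_transform_power(1.0) == 0.0
        assert fp.log_transform_power(np.e) == pytest.approx(1.0)
        assert fp.log_transform_power(5.0) > fp.log_transform_power(2.0)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            fp.log_transform_power(0.0)


class TestMinutePowers:
    def test_counts_per_phase_and_bad_channel_absent(self, synth_phase_set):
        quality = fp.ChannelQuality(
            status={"AF7": "good", "Fp1": "good", "Fp2": "good", "AF8": "bad"}
        )
        df, _ = fp.eeg_minute_powers(synth_phase_set, quality)
        assert "AF8" not in set(df["channel"])
        flow = df[(df.phase == "flow") & (df.band == "alpha")]
        assert sorted(flow[flow.channel == "Fp1"]["minute"]) == list(range(1, 9))
        bl = df[df.phase == "baseline_closed"]
        assert set(bl["minute"]) == {1}
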