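"""Coherence estimation, confidence levels, band summaries and laterality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sp_signal

import myocoh as mc
from myocoh.errors import (
    DegenerateError,
    MontageError,
    ParameterError,
    QualityError,
    ScheduleError,
)


def band_noise(rng, n, rate, low, high):
    x = rng.standard_normal(n)
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    y = sp_signal.sosfiltfilt(sos, x)
    return y / y.std()


class TestConfidenceLevel:
    def test_l2_is_alpha_complement(self):
        assert mc.confidence_level(2) == pytest.approx(0.95)

    def test_l21_printed_formula(self):
        assert mc.confidence_level(21) == pytest.approx(0.1391083, abs=1e-6)

    def test_degenerate_alpha(self):
        assert mc.confidence_level(10, alpha=1.0) == pytest.approx(0.0)

    def test_strictly_decreasing_in_l(self):
        values = [mc.confidence_level(L) for L in range(2, 200)]
        assert np.all(np.diff(values) < 0)

    def test_l_below_two_rejected(self):
        with pytest.raises(ParameterError):
            mc.confidence_level(1)


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(8000)
        profile = mc.compute_coherence(x, x)
        np.testing.assert_allclose(profile.coherence[1:-1], 1.0, atol=1e-9)

    def test_rescaling_invariance(self, rng):
        x = rng.standard_normal(8000)
        y = rng.standard_normal(8000) + 0.5 * x
        p1 = mc.compute_coherence(x, y)
        p2 = mc.compute_coherence(3.0 * x, -0.2 * y)
        np.testing.assert_allclose(p1.coherence, p2.coherence, atol=1e-12)

    def test_bounded_unit_interval(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        profile = mc.compute_coherence(x, y)
        assert (profile.coherence >= 0).all() and (profile.coherence <= 1).all()

    def test_independent_noise_exceedance_rate(self):
        """Under independence the default confidence level is a valid
        (conservative) false-positive bound, while the raw overlapped
        segment count is anticonservative.

        With Hann windows at 75% overlap the variance-equivalent number of
        independent segments lies between floor(N/W) and the raw Welch
        count, so floor(N/W) overstates the threshold (measured exceedance
        ~0.1% << alpha) and the raw count understates it (~22%).
        """
        frac_independent, frac_overlapped = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x, y = r.standard_normal(60000), r.standard_normal(60000)
            p_ind = mc.compute_coherence(x, y)
            p_ov = mc.compute_coherence(x, y, segment_count="overlapped")
            frac_independent.append(np.mean(p_ind.coherence > p_ind.confidence))
            frac_overlapped.append(np.mean(p_ov.coherence > p_ov.confidence))
        assert np.mean(frac_independent) <= 0.05
        assert np.mean(frac_overlapped) > 0.05

    def test_shared_narrowband_source_peak_location(self, rng):
        n, rate = 60000, 1000.0
        s = band_noise(rng, n, rate, 19.0, 21.0)
        x = s + 0.5 * rng.standard_normal(n)
        y = s + 0.5 * rng.standard_normal(n)
        profile = mc.compute_coherence(x, y, rate)
        band = (profile.freqs >= 12) & (profile.freqs <= 30)
        peak = profile.freqs[band][np.argmax(profile.coherence[band])]
        assert abs(peak - 20.0) <= 4.0

    def test_segment_count_modes(self, rng):
        x = rng.standard_normal(1280)
        y = rng.standard_normal(1280)
        independent = mc.compute_coherence(x, y)
        overlapped = mc.compute_coherence(x, y, segment_count="overlapped")
        assert independent.L == 10
        assert overlapped.L == 1 + (1280 - 128) // 32
        assert overlapped.confidence < independent.confidence

    def test_too_short_rejected(self, rng):
        with pytest.raises(ScheduleError):
            mc.compute_coherence(rng.standard_normal(200), rng.standard_normal(200))


class TestBetaSummary:
    @staticmethod
    def _profile(coherence, freqs=None, L=20):
        freqs = (
            np.asarray(freqs)
            if freqs is not None
            else np.linspace(0, 500, coherence.size)
        )
        return mc.CoherenceProfile(
            freqs=freqs,
            coherence=np.asarray(coherence, dtype=float),
            L=L,
            confidence=mc.confidence_level(L),
        )

    def test_zero_coherence_zero_score(self):
        profile = self._profile(np.zeros(65))
        assert mc.beta_band_summary(profile).stouffer_z == pytest.approx(0.0)

    def test_uniform_coherence_closed_form(self):
        L, c = 20, 0.3
        freqs = np.linspace(0, 100, 51)  # 2 Hz spacing
        profile = self._profile(np.full(51, c), freqs=freqs, L=L)
        summary = mc.beta_band_summary(profile)
        K = np.sum((freqs >= 12) & (freqs <= 30))
        expected = np.arctanh(np.sqrt(c)) * np.sqrt(2 * L) * np.sqrt(K)
        assert summary.stouffer_z == pytest.approx(expected)
        assert summary.peak_coherence == pytest.approx(c)
        assert summary.peak_freq == pytest.approx(12.0)  # tie -> lowest freq

    def test_spike_sets_peak(self):
        freqs = np.linspace(0, 100, 101)
        coherence = np.zeros(101)
        coherence[24] = 0.8  # 24 Hz
        profile = self._profile(coherence, freqs=freqs)
        summary = mc.beta_band_summary(profile)
        assert summary.peak_freq == pytest.approx(24.0)
        assert summary.peak_coherence == pytest.approx(0.8)

    def test_empty_band_rejected(self):
        profile = self._profile(np.zeros(65))
        with pytest.raises(ParameterError):
            mc.beta_band_summary(profile, band=(30.0, 12.0))


class TestLaterality:
    def test_contralesional_silence_boundary(self):
        assert mc.laterality(1.5, 0.0).value == pytest.approx(1.0)

    def test_symmetry_zero(self):
        assert mc.laterality(2.0, 2.0).value == pytest.approx(0.0)

    @given(a=st.floats(0.0, 50.0), b=st.floats(0.0, 50.0))
    def test_antisymmetry_and_bounds(self, a, b):
        if a + b <= 0:
            with pytest.raises(DegenerateError):
                mc.laterality(a, b)
            return
        res = mc.laterality(a, b)
        assert -1.0 <= res.value <= 1.0
        assert mc.laterality(b, a).value == pytest.approx(-res.value)

    def test_zero_total_undefined(self):
        with pytest.raises(DegenerateError):
            mc.laterality(0.0, 0.0)


class TestBadChannelsAndPreprocess:
    def test_spike_channel_flagged(self, rng):
        samples = rng.standard_normal((11, 5000))
        spikes = np.zeros(5000)
        spikes[rng.integers(0, 5000, 12)] = 40.0
        samples[4] = spikes
        rec = mc.Recording(
            samples, 500.0, tuple(f"ch{i}" for i in range(11)), ("EEG",) * 11
        )
        assert mc.detect_bad_channels(rec) == ["ch4"]

    def test_flatline_flagged(self, rng):
        samples = rng.standard_normal((6, 4000))
        samples[2] = 0.25  # constant
        rec = mc.Recording(
            samples, 500.0, tuple("abcdef"), ("EEG",) * 6
        )
        assert "c" in mc.detect_bad_channels(rec)

    def test_gaussian_montage_rarely_flagged(self):
        flagged = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            rec = mc.Recording(
                r.standard_normal((10, 5000)),
                500.0,
                tuple(f"ch{i}" for i in range(10)),
                ("EEG",) * 10,
            )
            if mc.detect_bad_channels(rec):
                flagged += 1
        assert flagged <= 5

    def test_car_zero_mean_identity(self, coupled_session):
        _, eeg, _, _ = coupled_session
        car, _ = mc.preprocess_eeg(eeg, zscore=False)
        assert np.abs(car.samples.mean(axis=0)).max() < 1e-10

    def test_zscore_identity(self, coupled_session):
        _, eeg, _, _ = coupled_session
        clean, _ = mc.preprocess_eeg(eeg)
        np.testing.assert_allclose(clean.samples.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(clean.samples.std(axis=1), 1.0, atol=1e-9)

    def test_injected_flatline_removed(self, coupled_session):
        _, eeg, _, _ = coupled_session
        bad, labels = mc.inject_artifacts(eeg, 2, seed=7)
        _, removed = mc.preprocess_eeg(bad)
        assert set(labels) <= set(removed)

    def test_majority_bad_is_quality_error(self, rng):
        samples = rng.standard_normal((6, 4000))
        samples[:4] = 0.0  # four flatlines of six
        rec = mc.Recording(samples, 500.0, tuple("abcdef"), ("EEG",) * 6)
        with pytest.raises(QualityError):
            mc.preprocess_eeg(rec)


class TestEMGForCMC:
    def test_envelope_recovery(self, rng):
        """Hilbert magnitude tracks a slow programmed amplitude envelope."""
        rate, n = 2148.0, int(2148 * 10)
        t = np.arange(n) / rate
        programmed = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        carrier = band_noise(rng, n, rate, 20.0, 450.0)
        rec = mc.Recording((programmed * carrier)[None, :], rate, ("m",), ("EMG",))
        out = mc.emg_for_cmc(rec)
        sos = sp_signal.butter(4, 8.0, btype="lowpass", fs=rate, output="sos")
        smoothed = sp_signal.sosfiltfilt(sos, out.samples[0])
        core = slice(4000, -4000)
        r = np.corrcoef(smoothed[core], programmed[core])[0, 1]
        assert r >= 0.9

    def test_zscore_identity(self, rng):
        rec = mc.Recording(
            band_noise(rng, 10000, 2148.0, 20.0, 450.0)[None, :],
            2148.0,
            ("m",),
            ("EMG",),
        )
        out = mc.emg_for_cmc(rec)
        assert out.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.samples.std() == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_degenerate(self):
        rec = mc.Recording(np.zeros((1, 10000)), 2148.0, ("m",), ("EMG",))
        with pytest.raises(DegenerateError):
            mc.emg_for_cmc(rec)


class TestFallback:
    def test_present_is_identity(self):
        assert mc.electrode_fallback("C3", [], ["C3", "CP1"]) == "C3"

    def test_priority_order(self):
        available = ["FC1", "CP1", "CP5", "C4"]
        assert mc.electrode_fallback("C3", ["C3"], available) == "CP1"
        assert mc.electrode_fallback("C3", ["C3", "CP1"], available) == "FC1"

    def test_hemisphere_exhausted(self):
        with pytest.raises(MontageError):
            mc.electrode_fallback("C3", ["C3", "CP1", "FC1", "CP5", "FC5"], ["C4"])

    def test_non_motor_request_rejected(self):
        with pytest.raises(ParameterError):
            mc.electrode_fallback("FC1", [], ["FC1"])


class TestCMCPipeline:
    def test_asymmetric_coupling_positive_laterality(
        self, coupled_session, channel_map
    ):
        _, eeg, emg, params = coupled_session
        res = mc.cmc_pipeline(eeg, emg, channel_map, params["schedule"])
        assert res.laterality.value > 0
        assert res.electrodes == {"ipsilesional": "C3", "contralesional": "C4"}
        assert (
            res.summaries["ipsilesional"].stouffer_z
            > res.summaries["contralesional"].stouffer_z
        )

    def test_equal_gains_near_symmetric(self, channel_map):
        cfg = mc.SynthSignalConfig(
            seed=21, ipsilesional_gain=1.0, contralesional_gain=1.0
        )
        eeg, emg, params = mc.generate_coupled_eeg_emg(cfg)
        res = mc.cmc_pipeline(eeg, emg, channel_map, params["schedule"])
        assert abs(res.laterality.value) < 0.15

    def test_bad_motor_electrode_uses_neighbour(self, coupled_session, channel_map):
        _, eeg, emg, params = coupled_session
        bad = eeg.samples.copy()
        bad[eeg.labels.index("C3")] = 0.0  # flatline the ipsilesional electrode
        eeg_bad = mc.Recording(bad, eeg.rate, eeg.labels, eeg.modalities)
        res = mc.cmc_pipeline(eeg_bad, emg, channel_map, params["schedule"])
        assert "C3" in res.removed_channels
        assert res.electrodes["ipsilesional"] == "CP1"

    def test_peak_frequency_near_programmed_source(
        self, coupled_session, channel_map
    ):
        _, eeg, emg, params = coupled_session
        res = mc.cmc_pipeline(eeg, emg, channel_map, params["schedule"])
        assert abs(
            res.summaries["ipsilesional"].peak_freq - params["beta_source_freq"]
        ) <= 4.0
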