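"""Laplacian reference, FIR band-pass, epoching, averaging, periodogram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from ssvepkit.preprocess import (
    average_epochs,
    bandpass_filter,
    design_bandpass,
    extract_epochs,
    laplacian_reference,
    power_spectrum,
)
from ssvepkit.synth import ContinuousRecording, make_stim_schedule

FS = 256.0


def _recording(oz, o1, o2, fs=FS):
    sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=fs)
    return ContinuousRecording(
        channels={"Oz": np.asarray(oz, float), "O1": np.asarray(o1, float), "O2": np.asarray(o2, float)},
        sampling_rate=fs,
        events=sch,
    )


class TestLaplacian:
    def test_zero_reference_passes_oz_through(self):
        s = np.arange(10.0)
        rec = _recording(s, np.zeros(10), np.zeros(10))
        assert np.array_equal(laplacian_reference(rec), s)

    def test_common_mode_is_rejected_exactly(self):
        s = np.sin(np.arange(10.0))
        rec = _recording(s, s, s)
        assert np.allclose(laplacian_reference(rec), 0.0)

    def test_hand_arithmetic(self):
        rec = _recording([1.0, 2.0], [0.0, 2.0], [2.0, 0.0])
        assert np.array_equal(laplacian_reference(rec), [0.0, 1.0])

    def test_missing_channel_error_names_it(self):
        rec = _recording(np.zeros(4), np.zeros(4), np.zeros(4))
        del rec.channels["O1"]
        with pytest.raises(KeyError, match="O1"):
            laplacian_reference(rec)

    def test_channel_names_matched_case_insensitively(self):
        rec = _recording(np.ones(4), np.zeros(4), np.zeros(4))
        rec.channels = {"OZ": rec.channels.pop("Oz"), "o1": rec.channels.pop("O1"), "o2": rec.channels.pop("O2")}
        assert np.array_equal(laplacian_reference(rec), np.ones(4))


class TestBandpass:
    def test_in_band_tone_amplitude_preserved_within_one_percent(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 15.0 * t)
        y = bandpass_filter(x, sampling_rate=FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.abs(np.ptp(y[mid]) / np.ptp(x[mid]) - 1.0) < 0.01

    def test_dc_removed(self):
        x = np.ones(int(30 * FS))
        y = bandpass_filter(x, sampling_rate=FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.max(np.abs(y[mid])) < 0.01

    @pytest.mark.parametrize("freq", [1.0, 50.0])
    def test_stopband_attenuation_at_least_40_db(self, freq):
        taps = design_bandpass(4.0, 40.0, FS)
        w, h = sps.freqz(taps, worN=16384, fs=FS)
        gain_db = 20 * np.log10(np.abs(h[np.argmin(np.abs(w - freq))]) + 1e-300)
        assert gain_db <= -40.0

    def test_zero_phase_no_delay_for_in_band_tone(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 15.0 * t)
        y = bandpass_filter(x, sampling_rate=FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        # phase preserved -> pointwise agreement, not just envelope
        assert np.max(np.abs(y[mid] - x[mid])) < 0.02

    def test_signal_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bandpass_filter(np.zeros(100), sampling_rate=FS)


class TestEpoching:
    def test_every_event_yields_exactly_one_epoch(self):
        sch = make_stim_schedule(n_cycles=20, seed=3, sampling_rate=FS)
        sig = np.zeros(sch.end_sample + 10)
        es = extract_epochs(sig, sch)
        assert es.n_epochs_total == sch.n_events == 160
        assert len(es.epochs) == 8
        assert all(arr.shape == (20, int(3 * FS)) for arr in es.epochs.values())

    def test_epoch_length_at_native_rate(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=2048.0)
        sig = np.zeros(sch.end_sample)
        es = extract_epochs(sig, sch)
        assert next(iter(es.epochs.values())).shape[1] == 6144  # 3 s x 2048 Hz

    def test_truncated_final_epoch_raises_with_event(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=FS)
        sig = np.zeros(sch.end_sample - 1)
        with pytest.raises(ValueError, match="onset"):
            extract_epochs(sig, sch)

    def test_epochs_start_exactly_at_marker(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=1, sampling_rate=FS)
        sig = np.zeros(sch.end_sample + 5)
        for ev in sch.events:
            sig[ev.onset_sample] = ev.cycle  # tag first sample
        es = extract_epochs(sig, sch)
        for key, arr in es.epochs.items():
            assert np.all(arr[:, 0] > 0)


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self):
        sch = make_stim_schedule([4.47], n_cycles=4, seed=0, sampling_rate=FS)
        sig = np.sin(np.arange(sch.end_sample) / 7.0)
        es = extract_epochs(sig, sch)
        key = next(iter(es.keys()))
        es.epochs[key] = np.tile(es.epochs[key][0], (8, 1))
        avg = average_epochs(es)
        assert np.allclose(avg[key], es.epochs[key][0])

    def test_noise_variance_shrinks_as_one_over_n(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(40):
            eps = rng.standard_normal((20, 400))
            ratios.append(eps.mean(axis=0).var() / eps.var())
        assert np.mean(ratios) == pytest.approx(1 / 20, rel=0.3)

    def test_run_subset_averages_ten_epochs(self):
        sch = make_stim_schedule([4.47], n_cycles=20, seed=0, sampling_rate=FS)
        sig = np.zeros(sch.end_sample)
        es = extract_epochs(sig, sch)
        key = next(iter(es.keys()))
        assert (es.runs[key] == 1).sum() == 10
        avg = average_epochs(es, run=1)
        assert avg[key].shape == (int(3 * FS),)

    def test_missing_run_raises(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=FS)
        es = extract_epochs(np.zeros(sch.end_sample), sch)
        with pytest.raises(ValueError, match="no epochs"):
            average_epochs(es, run=9)


class TestPowerSpectrum:
    def test_exact_bin_tone_is_leakage_free(self):
        n = int(3 * 2048)
        t = np.arange(n) / 2048.0
        x = np.sin(2 * np.pi * 15.0 * t)  # 45 integer cycles in 3 s
        psd = power_spectrum(x, 2048.0)
        b = psd.bin_index(15.0)
        assert b == 45
        assert psd.power[b] == pytest.approx(0.5, rel=1e-9)  # A^2/2
        neighbours = np.delete(np.arange(40, 51), 5)
        assert np.all(psd.power[neighbours] < 1e-20)

    def test_zero_signal_gives_all_zero_power(self):
        psd = power_spectrum(np.zeros(768), FS)
        assert np.all(psd.power == 0.0)

    def test_amplitude_scaling_is_square_law(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(768)
        p1 = power_spectrum(x, FS).power
        p3 = power_spectrum(3.0 * x, FS).power
        assert np.allclose(p3, 9.0 * p1)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=16, max_value=700), st.integers(0, 2**31 - 1))
    def test_parseval_identity(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        psd = power_spectrum(x, FS, check_on_grid=None)
        assert np.sum(psd.power) == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_off_grid_reversal_rate_warns(self):
        with pytest.warns(UserWarning, match="bin centre"):
            power_spectrum(np.zeros(700), FS, check_on_grid=15.0)

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([]), FS)
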