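"""Stimulus schedules, cohorts, the SNR oracle and the forward model."""

import numpy as np
import pytest
from scipy import stats as sstats

from ssvepkit.synth import (
    DEFAULT_SF_GRID,
    AcuityLink,
    GroundTruth,
    StimCondition,
    amplitude_for_snr,
    expected_snr_oracle,
    make_stim_schedule,
    sample_cohort,
    simulate_recording,
)
from .conftest import make_eye_truth, simulate_eye


class TestStimCondition:
    def test_fractional_reversal_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            StimCondition(1.0, reversal_rate=15.0, duration=3.1)

    def test_reversal_rate_must_stay_in_analysis_band(self):
        with pytest.raises(ValueError):
            StimCondition(1.0, reversal_rate=45.0)

    def test_negative_spatial_frequency_rejected(self):
        with pytest.raises(ValueError):
            StimCondition(-0.5)


class TestSchedule:
    def test_event_count_seven_gratings_plus_flicker(self):
        sch = make_stim_schedule(DEFAULT_SF_GRID, n_cycles=20, seed=0)
        assert sch.n_events == 20 * 8

    def test_run_labels_split_cycles_in_half(self):
        sch = make_stim_schedule(DEFAULT_SF_GRID, n_cycles=20, seed=0)
        runs = {ev.cycle: ev.run for ev in sch.events}
        assert all(runs[c] == 1 for c in range(1, 11))
        assert all(runs[c] == 2 for c in range(11, 21))

    def test_gratings_ascend_with_flicker_last_within_each_cycle(self):
        sch = make_stim_schedule(DEFAULT_SF_GRID, n_cycles=4, seed=1)
        for cycle in range(1, 5):
            sfs = [ev.condition.spatial_frequency for ev in sch.events if ev.cycle == cycle]
            assert sfs[:-1] == sorted(sfs[:-1]) and sfs[-1] == 0.0

    def test_gaps_jittered_between_three_and_five_seconds(self):
        sch = make_stim_schedule(DEFAULT_SF_GRID, n_cycles=4, seed=2, sampling_rate=256.0)
        onsets = np.array([ev.onset_sample for ev in sch.events])
        gaps = np.diff(onsets) / 256.0 - 3.0  # minus stimulus duration
        assert np.all(gaps >= 3.0 - 1e-9) and np.all(gaps <= 5.0 + 1e-9)

    def test_same_seed_reproduces_onsets(self):
        a = make_stim_schedule(seed=7)
        b = make_stim_schedule(seed=7)
        assert [ev.onset_sample for ev in a.events] == [ev.onset_sample for ev in b.events]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sf_list": [2.0, 1.0]},
            {"sf_list": []},
            {"sf_list": [0.0, 1.0]},
            {"jitter_range": (1.0, 5.0)},
            {"n_cycles": 5},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_stim_schedule(**kwargs)


class TestCohort:
    def test_cohort_size_three_groups_two_eyes(self):
        cohort, truth = sample_cohort(18, seed=0)
        assert len(cohort) == 108 and len(truth) == 108
        assert cohort.groupby("participant_id")["eye"].count().eq(2).all()
        assert cohort.groupby("participant_id")["group"].nunique().eq(1).all()

    def test_noiseless_monotone_link_gives_perfect_rank_correlation(self):
        link = AcuityLink(noise_sd=0.0, categorical=False)
        cohort, truth = sample_cohort(10, acuity_link=link, seed=1)
        for g, sub in cohort.groupby("group"):
            gains = [truth[(r.participant_id, r.eye)].g_max for r in sub.itertuples()]
            acuity = sub["acuity_raw"].astype(float).to_numpy()
            unclipped = (acuity > -0.3 + 1e-9) & (acuity < 2.7 - 1e-9)
            rho = sstats.spearmanr(np.asarray(gains)[unclipped], acuity[unclipped]).statistic
            assert rho == pytest.approx(-1.0)

    def test_eyes_of_one_participant_share_the_gain_random_effect(self):
        gt = GroundTruth(participant_gain_sd=2.0, eye_gain_sd=0.5)
        _, truth = sample_cohort(40, ground_truth=gt, seed=2, groups=("Control",))
        pairs = {}
        for (pid, eye), et in truth.items():
            pairs.setdefault(pid, {})[eye] = et.g_max
        os_g = [v["OS"] for v in pairs.values()]
        od_g = [v["OD"] for v in pairs.values()]
        assert np.corrcoef(os_g, od_g)[0, 1] > 0.5

    def test_zero_participant_effect_decorrelates_eyes(self):
        gt = GroundTruth(participant_gain_sd=0.0, eye_gain_sd=1.0)
        _, truth = sample_cohort(60, ground_truth=gt, seed=3, groups=("Control",))
        pairs = {}
        for (pid, eye), et in truth.items():
            pairs.setdefault(pid, {})[eye] = et.g_max
        r = np.corrcoef([v["OS"] for v in pairs.values()], [v["OD"] for v in pairs.values()])[0, 1]
        assert abs(r) < 0.25

    def test_negative_acuity_noise_rejected(self):
        with pytest.raises(ValueError):
            AcuityLink(noise_sd=-0.1)


class TestSnrOracle:
    def test_zero_amplitude_expects_zero_db(self):
        assert expected_snr_oracle(0.0, 1.0, 20) == pytest.approx(0.0)

    def test_tenfold_signal_power_gives_ten_point_four_db(self):
        # signal power 10x the per-bin noise power after averaging
        noise, n = 0.5, 20
        amp = np.sqrt(2.0 * 10.0 * noise / n)
        assert expected_snr_oracle(amp, noise, n) == pytest.approx(10 * np.log10(11), abs=1e-12)

    def test_snr_grows_monotonically_with_averaged_epochs(self):
        vals = [expected_snr_oracle(1.0, 1.0, n) for n in (1, 2, 5, 20, 40)]
        assert np.all(np.diff(vals) > 0)

    def test_amplitude_inversion_round_trips(self):
        amp = amplitude_for_snr(12.0, 0.8, 20)
        assert expected_snr_oracle(amp, 0.8, 20) == pytest.approx(12.0)
        assert amplitude_for_snr(-5.0, 0.8, 20) == 0.0

    @pytest.mark.parametrize("bad", [dict(noise_psd_at_band=0.0), dict(n_averaged_epochs=0)])
    def test_degenerate_inputs_rejected(self, bad):
        kwargs = dict(signal_amplitude=1.0, noise_psd_at_band=1.0, n_averaged_epochs=20)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            expected_snr_oracle(**kwargs)


class TestForwardModel:
    def test_same_seed_gives_bit_identical_recordings(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=256.0)
        et = make_eye_truth()
        a = simulate_recording(sch, et, seed=5)
        b = simulate_recording(sch, et, seed=5)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_event_past_recording_end_rejected(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=256.0)
        with pytest.raises(ValueError, match="past"):
            simulate_recording(sch, make_eye_truth(), seed=0, n_samples=100)

    def test_single_strong_condition_dominates_the_curve(self):
        """A large response at one spatial frequency only shows up there."""
        et = make_eye_truth(g_max=18.0, beta=0.3)  # narrow peak at 4.2 cpd
        hits, others = [], []
        for seed in range(6):
            _, curve = simulate_eye(et, seed=100 + seed, sf_list=[0.5, 4.2, 13.33], n_cycles=20)
            snr = dict(zip(curve.spatial_frequencies, curve.snr))
            hits.append(snr[4.2])
            others.extend([snr[0.5], snr[13.33]])
        assert np.mean(hits) > 10.0
        # off-peak conditions hover at the noise floor (median robust to the
        # heavy lower tail of the log-ratio statistic)
        assert abs(np.median(others)) < 5.0

    def test_channel_lengths_are_whole_seconds(self):
        sch = make_stim_schedule([4.47], n_cycles=2, seed=0, sampling_rate=256.0)
        rec = simulate_recording(sch, make_eye_truth(), seed=1)
        assert rec.n_samples % 256 == 0
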