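"""Signal-conditioning chain: filtering, resampling, referencing,
artifact rejection, baseline correction, trial selection."""

import numpy as np
import pandas as pd
import pytest

from wmgating import preprocess as pp
from wmgating.preprocess import EpochSet


def tone(freq, fs, n, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def fft_amplitude(x, fs, freq):
    spec = np.abs(np.fft.rfft(x)) / len(x) * 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


def make_epochs(data, fs=256.0, t0=-200.0, condition=None):
    n_trials, _, n_samples = data.shape
    times = t0 + np.arange(n_samples) * (1000.0 / fs)
    condition = condition or ["switch_reference"] * n_trials
    return EpochSet(data=data, fs=fs, times=times, condition=np.array(condition, dtype=object))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        fs = 500.0
        x = tone(10.0, fs, 20000)
        y = pp.bandpass_filter(x, fs)
        assert abs(fft_amplitude(y, fs, 10.0) - 1.0) < 0.05

    def test_sub_band_tone_strongly_attenuated(self):
        fs = 500.0
        x = tone(0.1, fs, 100000)
        y = pp.bandpass_filter(x, fs)
        # 0.1 Hz sits >2 octaves below the 0.5 Hz edge at 48 dB/oct
        assert fft_amplitude(y, fs, 0.1) < 0.1

    def test_dc_removed(self):
        y = pp.bandpass_filter(np.full(8000, 5.0), 500.0)
        assert np.abs(y).max() < 0.05

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass_filter(np.zeros(100), fs=500.0, lp=260.0)
        with pytest.raises(ValueError):
            pp.bandpass_filter(np.zeros(100), fs=500.0, hp=45.0, lp=40.0)


class TestResample:
    def test_length_ratio_500_to_256(self):
        y = pp.resample(np.zeros(5000), 500.0, 256.0)
        assert len(y) == 2560

    def test_identity_when_rates_equal(self):
        x = np.random.default_rng(0).normal(size=300)
        np.testing.assert_allclose(pp.resample(x, 256.0, 256.0), x)

    def test_tone_survives_resampling(self):
        fs = 500.0
        x = tone(20.0, fs, 50000)
        y = pp.resample(x, fs, 256.0)
        assert abs(fft_amplitude(y, 256.0, 20.0) - 1.0) < 0.02

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            pp.resample(np.zeros(100), 256.0, 500.0)

    def test_filter_and_resample_commute_on_bandlimited_signal(self):
        fs = 500.0
        x = tone(12.0, fs, 50000) + 0.5 * tone(25.0, fs, 50000)
        a = pp.resample(pp.bandpass_filter(x, fs), fs, 250.0)
        b = pp.bandpass_filter(pp.resample(x, fs, 250.0), 250.0)
        # compare steady state; filtfilt edge transients differ by rate
        a, b = a[500:-500], b[500:-500]
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
        assert rms < 0.02


class TestAverageReference:
    def test_constant_channels_become_zero(self):
        ep = make_epochs(np.full((2, 4, 50), 5.0))
        assert np.abs(pp.average_reference(ep).data).max() < 1e-12

    def test_channel_mean_zero_and_idempotent(self, rng):
        ep = make_epochs(rng.normal(size=(3, 6, 40)))
        once = pp.average_reference(ep)
        assert np.abs(once.data.mean(axis=1)).max() < 1e-9
        twice = pp.average_reference(once)
        np.testing.assert_allclose(twice.data, once.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.average_reference(make_epochs(np.zeros((1, 1, 50))))


class TestArtifactRejection:
    def _quiet(self, n_trials=3, fs=256.0, n=600):
        t = np.arange(n) / fs
        base = 10.0 * np.sin(2 * np.pi * 10.0 * t)
        return np.tile(base, (n_trials, 4, 1))

    def test_clean_sinusoid_kept(self):
        ep = make_epochs(self._quiet(), t0=-400.0)
        assert pp.reject_artifacts(ep).kept_mask.all()

    def test_flat_epoch_fails_low_activity(self):
        data = self._quiet()
        data[1] = 0.0
        kept = pp.reject_artifacts(make_epochs(data, t0=-400.0)).kept_mask
        assert list(kept) == [True, False, True]

    def test_absolute_amplitude_limit(self):
        data = self._quiet()
        data[0, 2, 300] = 250.0
        kept = pp.reject_artifacts(make_epochs(data, t0=-400.0)).kept_mask
        assert list(kept) == [False, True, True]

    def test_fast_peak_to_peak_limit(self):
        data = self._quiet()
        # 150 uV swing within a few samples stays inside +-200 uV but
        # breaks the 200 uV / 200 ms peak-to-peak budget... use +-110
        data[2, 1, 300:305] += 110.0
        data[2, 1, 305:310] -= 110.0
        kept = pp.reject_artifacts(make_epochs(data, t0=-400.0)).kept_mask
        assert list(kept) == [True, True, False]

    def test_rejection_is_per_trial_order_independent(self, rng):
        data = 10.0 + rng.normal(0, 5, size=(6, 4, 600))
        data[3, 0, 100] = 500.0
        ep = make_epochs(data, t0=-400.0)
        kept = pp.reject_artifacts(ep).kept_mask
        perm = rng.permutation(6)
        kept_perm = pp.reject_artifacts(
            make_epochs(data[perm], t0=-400.0)
        ).kept_mask
        assert np.array_equal(kept[perm], kept_perm)


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = make_epochs(np.full((2, 3, 256), 5.0))
        out = pp.baseline_correct(ep, window=(-200.0, 0.0))
        assert np.abs(out.data).max() < 1e-12

    def test_shift_subtracted_from_post_stimulus_samples(self):
        data = np.zeros((1, 1, 256))
        times = -200.0 + np.arange(256) * (1000.0 / 256.0)
        data[0, 0, times <= 0] = 2.0
        k = np.argmin(np.abs(times - 400.0))
        data[0, 0, k] = 10.0
        out = pp.baseline_correct(make_epochs(data), window=(-200.0, 0.0))
        assert abs(out.data[0, 0, k] - 8.0) < 1e-9
        sel = (times >= -200.0) & (times <= 0.0)
        assert abs(out.data[0, 0, sel].mean()) < 1e-9

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            pp.baseline_correct(
                make_epochs(np.zeros((1, 2, 100))), window=(-900.0, -800.0)
            )


class TestTrialSelection:
    def test_counts_after_mixed_outcomes(self):
        data = np.zeros((10, 2, 50))
        ep = make_epochs(data, t0=-100.0)
        rt = [300.0] * 10
        correct = [True] * 10
        for i in (1, 4, 7):
            correct[i] = False
        rt[9] = 1600.0  # late response
        beh = pd.DataFrame(
            {
                "rt_ms": rt,
                "correct": correct,
                "condition": ["switch_reference"] * 10,
            }
        )
        out = pp.select_correct_trials(ep, beh)
        assert out.n_trials == 6

    def test_alignment_mismatch_rejected(self):
        ep = make_epochs(np.zeros((3, 2, 50)))
        beh = pd.DataFrame({"rt_ms": [1.0], "correct": [True], "condition": ["x"]})
        with pytest.raises(ValueError):
            pp.select_correct_trials(ep, beh)

    def test_all_incorrect_yields_empty_with_warning(self):
        ep = make_epochs(np.zeros((3, 2, 50)))
        beh = pd.DataFrame(
            {
                "rt_ms": [300.0] * 3,
                "correct": [False] * 3,
                "condition": ["switch_reference"] * 3,
            }
        )
        with pytest.warns(UserWarning):
            out = pp.select_correct_trials(ep, beh)
        assert out.n_trials == 0


def test_low_trial_subject_flagging():
    counts = pd.DataFrame(
        {
            "switch_reference": [60, 30],
            "nonswitch_reference": [120, 120],
            "switch_comparison": [70, 70],
            "nonswitch_comparison": [110, 110],
        },
        index=["S00", "S01"],
    )
    assert pp.flag_low_trial_subjects(counts, min_trials=50) == ["S01"]


def test_container_roundtrip(tmp_path, rng):
    ep = make_epochs(rng.normal(size=(4, 3, 64)), condition=["switch_reference",
        "nonswitch_reference", "switch_comparison", "nonswitch_comparison"])
    ep.kept_mask[2] = False
    path = tmp_path / "epochs.h5"
    ep.save(path)
    back = EpochSet.load(path)
    np.testing.assert_allclose(back.data, ep.data)
    np.testing.assert_allclose(back.times, ep.times)
    assert list(back.condition) == list(ep.condition)
    assert np.array_equal(back.kept_mask, ep.kept_mask)
    assert back.fs == ep.fs and back.subject == ep.subject
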