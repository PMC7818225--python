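import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from erprep.preprocess import (PreprocConfig, average_by_condition, bandpass_filter,
                               baseline_correct, exclude_near_target, filter_response_db,
                               preprocess, reject_artifacts, rereference_common_average)
from erprep.simulate import EpochSet, SimulationConfig, inject_artifacts, simulate_subject


def make_epochs(montage, data, times=None, blocks=None, pres=None, onsets=None):
    n_tr = data.shape[0]
    times = times if times is not None else -100.0 + 4.0 * np.arange(data.shape[2])
    trials = pd.DataFrame(
        {
            "subject": 0,
            "block": blocks if blocks is not None else np.ones(n_tr, int),
            "object": np.arange(n_tr),
            "presentation": pres if pres is not None else np.ones(n_tr, int),
            "onset_ms": onsets if onsets is not None else 570.0 * np.arange(n_tr),
        }
    )
    return EpochSet(data=data, times_ms=times, montage=montage, trials=trials)


class TestBandpass:
    def test_dc_removed(self, montage):
        data = np.full((2, 65, 400), 7.0)
        out = bandpass_filter(make_epochs(montage, data))
        assert np.abs(out.data).max() < 0.07  # <1% of the DC amplitude

    def test_passband_tone_preserved(self, montage):
        t = np.arange(600) / 250.0
        tone = np.sin(2 * np.pi * 10.0 * t)
        data = np.tile(tone, (1, 65, 1))
        out = bandpass_filter(make_epochs(montage, data, times=1000 * t - 100))
        mid = slice(150, 450)
        ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(tone[mid]).max()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuation_matches_analytic_response(self, montage):
        fs = 500.0
        t = np.arange(2000) / fs
        tone = np.sin(2 * np.pi * 60.0 * t)
        data = np.tile(tone, (1, 65, 1))
        cfg = PreprocConfig()
        out = bandpass_filter(make_epochs(montage, data, times=1000 * t - 100), cfg)
        mid = slice(500, 1500)
        measured_db = 20 * np.log10(np.abs(out.data[0, 0, mid]).max())
        expected_db = filter_response_db(cfg, 60.0, fs)  # zero-phase (|H|^2) response
        assert abs(measured_db - expected_db) < 1.5
        # the configured 24 dB/octave single-pass roll-off doubles zero-phase:
        # one octave above the edge (60 vs 30 Hz) must sit near -48 dB
        assert -60.0 < expected_db < -40.0

    def test_band_above_nyquist_rejected(self, montage):
        data = np.zeros((1, 65, 400))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(make_epochs(montage, data), PreprocConfig(band_hz=(1.0, 200.0)))


class TestRereference:
    def test_two_channel_example_and_zero_mean(self, montage, rng):
        data = rng.normal(size=(3, 65, 50))
        data[0, montage.index("O1"), 0] = 3.0
        out = rereference_common_average(make_epochs(montage, data))
        scalp = out.data[:, :61, :]
        assert np.abs(scalp.mean(axis=1)).max() < 1e-9
        # EOG channels untouched
        assert np.array_equal(out.data[:, 61:, :], data[:, 61:, :])

    def test_idempotent(self, montage, rng):
        ep = make_epochs(montage, rng.normal(size=(2, 65, 30)))
        once = rereference_common_average(ep)
        twice = rereference_common_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_explicit_pair(self, montage):
        data = np.zeros((1, 65, 1))
        data[0, 0, 0], data[0, 1, 0] = 3.0, -1.0
        out = rereference_common_average(make_epochs(montage, data))
        # mean over all 61 scalp channels is 2/61
        assert np.isclose(out.data[0, 0, 0], 3.0 - 2.0 / 61)
        assert np.isclose(out.data[0, 1, 0], -1.0 - 2.0 / 61)


class TestBaseline:
    def test_constant_trial_zeroed(self, montage):
        data = np.full((1, 65, 200), 7.0)
        out = baseline_correct(make_epochs(montage, data), (-100.0, 0.0))
        assert np.abs(out.data).max() < 1e-12

    def test_window_mean_zero_and_idempotent(self, montage, rng):
        ep = make_epochs(montage, rng.normal(size=(4, 65, 200)))
        out = baseline_correct(ep, (-100.0, 0.0))
        sel = (out.times_ms >= -100) & (out.times_ms <= 0)
        assert np.abs(out.data[:, :, sel].mean(axis=2)).max() < 1e-9
        again = baseline_correct(out, (-100.0, 0.0))
        assert np.allclose(out.data, again.data, atol=1e-12)

    def test_window_outside_epoch_rejected(self, montage):
        ep = make_epochs(montage, np.zeros((1, 65, 10)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (-500.0, -400.0))


class TestRejection:
    def test_eog_excursion_rejects_trial(self, montage):
        data = np.zeros((3, 65, 100))
        data[1, 63, 50] = 80.0  # one EOG sample above threshold
        kept, rejected = reject_artifacts(make_epochs(montage, data), 75.0)
        assert list(rejected) == [1]
        assert kept.n_trials == 2
        assert list(kept.trials["object"]) == [0, 2]  # order preserved

    def test_all_within_threshold_keeps_everything(self, montage, rng):
        data = rng.uniform(-50, 50, size=(5, 65, 40))
        kept, rejected = reject_artifacts(make_epochs(montage, data), 75.0)
        assert rejected.size == 0 and kept.n_trials == 5

    def test_injected_artifact_fixture_exactly_rejected(self, montage, grid):
        cfg = SimulationConfig(
            n_subjects=1, n_blocks=4, n_objects_per_block=10, noise_sd_uv=2.0,
            sampling_rate_hz=250.0, seed=21,
        )  # 240 trials
        ep = simulate_subject(cfg, 0, montage=montage, grid=grid)
        corrupted, idx = inject_artifacts(ep, 0.1, 120.0, seed=5)
        kept, rejected = reject_artifacts(corrupted, 75.0)
        assert np.array_equal(rejected, idx)
        assert kept.n_trials == 240 - 24


class TestTargetExclusion:
    def test_no_targets_unchanged(self, montage, rng):
        ep = make_epochs(montage, rng.normal(size=(4, 65, 30)))
        out = exclude_near_target(ep, [], 800.0)
        assert out.n_trials == 4

    def test_horizon_boundaries(self, montage):
        data = np.zeros((3, 65, 10))
        # onsets 500, 900, 1700 ms after a target at 0
        ep = make_epochs(montage, data, onsets=np.array([500.0, 900.0, 1700.0]))
        out = exclude_near_target(ep, [0.0], 800.0)
        assert list(out.trials["onset_ms"]) == [900.0, 1700.0]


class TestAveraging:
    def test_mean_and_counts(self, montage):
        data = np.zeros((4, 65, 10))
        data[0, 0, 0], data[1, 0, 0] = 0.0, 2.0
        data[2, 0, 0], data[3, 0, 0] = 5.0, 5.0
        ep = make_epochs(
            montage, data, blocks=np.array([1, 1, 1, 1]), pres=np.array([1, 1, 2, 2])
        )
        avg = average_by_condition(ep)
        assert np.isclose(avg.cell(1, 1)[0, 0], 1.0)  # mean of 0 and 2
        assert np.isclose(avg.cell(1, 2)[0, 0], 5.0)  # two identical trials
        assert avg.counts.sum() == 4

    def test_empty_cell_named_in_error(self, montage):
        ep = make_epochs(
            montage, np.zeros((2, 65, 10)),
            blocks=np.array([1, 1]), pres=np.array([1, 3]),
        )
        with pytest.raises(ValueError, match=r"block=1, presentation=2"):
            average_by_condition(ep)

    def test_rejection_leaves_untouched_cells_unchanged(self, montage, rng):
        data = rng.normal(size=(8, 65, 20))
        blocks = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        pres = np.array([1, 1, 2, 2, 1, 1, 2, 2])
        ep = make_epochs(montage, data, blocks=blocks, pres=pres)
        before = average_by_condition(ep)
        spiked = data.copy()
        spiked[0, 5, 3] = 500.0  # corrupt one block-1 trial
        kept, _ = reject_artifacts(make_epochs(montage, spiked, blocks=blocks, pres=pres))
        after = average_by_condition(kept)
        assert np.allclose(after.cell(2, 1), before.cell(2, 1))
        assert np.allclose(after.cell(2, 2), before.cell(2, 2))


def test_full_preprocess_chain(montage, grid):
    cfg = SimulationConfig(
        n_subjects=1, n_blocks=4, n_objects_per_block=4, noise_sd_uv=2.0,
        sampling_rate_hz=250.0, seed=2,
    )
    ep = simulate_subject(cfg, 0, montage=montage, grid=grid)
    avg = preprocess(ep)
    assert avg.means.shape[:2] == (4, 6)
    assert avg.counts.min() >= 1
    assert "n_rejected" in avg.meta and "preproc" in avg.meta
    # averaged data is average-referenced: scalp mean ~ 0 at every sample
    assert np.abs(avg.means[:, :, :61, :].mean(axis=2)).max() < 1e-9
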