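"""Preprocessing chain: re-referencing, filtering, epoching, baseline,
amplitude rejection and the micro-time-window grid."""

import numpy as np
import pytest

from dynconn.preprocess import (
    EpochSet,
    Recording,
    bandpass,
    bandpass_array,
    baseline_correct,
    epoch,
    partition_windows,
    reject_artifacts,
    rereference,
)

FS = 500.0


def make_recording(data, channels=None):
    data = np.asarray(data, dtype=float)
    return Recording(data=data, fs=FS, channels=channels or [f"c{i}" for i in range(len(data))])


class TestRereference:
    def test_average_of_all_channels_zeros_the_sum(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 100)))
        out = rereference(rec, rec.channels)
        assert np.allclose(out.data.sum(axis=0), 0.0)

    def test_zero_reference_channels_leave_data_unchanged(self):
        data = np.vstack([np.zeros((2, 50)), np.random.default_rng(1).normal(size=(3, 50))])
        rec = make_recording(data, channels=["M1", "M2", "a", "b", "c"])
        out = rereference(rec, ["M1", "M2"])
        assert np.allclose(out.data, rec.data)

    def test_constant_mastoids_shift_all_channels(self):
        data = np.vstack([np.full(20, 1.0), np.full(20, 3.0), np.zeros(20)])
        rec = make_recording(data, channels=["M1", "M2", "x"])
        out = rereference(rec, ["M1", "M2"])
        assert np.allclose(out.data, rec.data - 2.0)

    def test_missing_label_is_named(self):
        rec = make_recording(np.zeros((2, 10)))
        with pytest.raises(KeyError, match="M9"):
            rereference(rec, ["M9"])


class TestBandpass:
    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(5000) / FS
        rec = make_recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bandpass(rec, "alpha")
        amp = out.data[0, 1000:4000].std() * np.sqrt(2)
        assert abs(amp - 1.0) < 0.05

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(5000) / FS
        rec = make_recording(np.sin(2 * np.pi * 20 * t)[None, :])
        out = bandpass(rec, "delta")
        amp = out.data[0, 1000:4000].std() * np.sqrt(2)
        assert amp < 0.1

    def test_dc_removed(self):
        rec = make_recording(np.full((1, 3000), 7.0))
        out = bandpass(rec, (1.0, 30.0))
        assert np.abs(out.data).max() < 0.1

    @pytest.mark.parametrize("band", [(0.0, 10.0), (10.0, 5.0), (10.0, 300.0)])
    def test_invalid_band_rejected(self, band):
        rec = make_recording(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            bandpass(rec, band)

    def test_nd_filtering_matches_per_row(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 4, 2000))
        batch = bandpass_array(x, 8, 13, FS)
        single = bandpass_array(x[1, 2], 8, 13, FS)
        assert np.allclose(batch[1, 2], single)


class TestEpoch:
    def test_epoch_window_sample_count(self):
        rec = make_recording(np.zeros((2, 10000)))
        ep = epoch(rec, [5000.0], (-650.0, 2500.0))
        assert ep.data.shape == (1, 2, 1575)
        assert ep.origin_ms == -650.0

    def test_no_events_gives_empty_epochset(self):
        rec = make_recording(np.zeros((2, 1000)))
        ep = epoch(rec, [], (-100.0, 100.0))
        assert ep.n_trials == 0

    def test_out_of_range_event_skipped(self, caplog):
        rec = make_recording(np.zeros((1, 1000)))
        with caplog.at_level("WARNING"):
            ep = epoch(rec, [0.0, 1000.0], (-100.0, 100.0), labels=["a", "b"])
        assert ep.n_trials == 1 and list(ep.labels) == ["b"]
        assert "skipped" in caplog.text


class TestBaseline:
    def test_constant_trial_becomes_zero(self):
        ep = EpochSet(np.full((2, 3, 500), 5.0), fs=FS, origin_ms=-650.0)
        out = baseline_correct(ep, (-650.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_baseline_leaves_trial_unchanged(self):
        data = np.zeros((1, 1, 400))
        data[0, 0, :100] = np.tile([1.0, -1.0], 50)  # zero-mean baseline
        data[0, 0, 100:] = 9.0
        ep = EpochSet(data, fs=FS, origin_ms=-650.0)
        out = baseline_correct(ep, (-650.0, -450.0))
        assert np.allclose(out.data, data)

    def test_ramp_baseline_mean_is_zero_after_correction(self):
        ep = EpochSet(np.arange(1575.0)[None, None, :], fs=FS, origin_ms=-650.0)
        out = baseline_correct(ep, (-650.0, 0.0))
        assert abs(out.data[0, 0, :325].mean()) < 1e-9

    def test_empty_interval_rejected(self):
        ep = EpochSet(np.zeros((1, 1, 100)), fs=FS, origin_ms=0.0)
        with pytest.raises(ValueError):
            baseline_correct(ep, (50.0, 50.0))


class TestRejection:
    def make_eps(self):
        data = np.zeros((3, 2, 100))
        data[0, 0, 10] = 80.0  # outside
        data[1, 1, 20] = 75.0  # exactly at the boundary
        data[2, 0, 30] = -74.9
        return EpochSet(data, fs=FS, labels=["a", "b", "c"])

    def test_threshold_crossing_trial_dropped(self):
        out, report = reject_artifacts(self.make_eps(), 75.0)
        assert report.n_dropped == 1 and out.n_trials == 2
        assert list(out.labels) == ["b", "c"]

    def test_boundary_value_retained(self):
        out, report = reject_artifacts(self.make_eps(), 75.0)
        assert report.kept[1]  # extremum exactly 75 µV survives

    def test_clean_set_untouched_and_totals_consistent(self):
        ep = EpochSet(np.random.default_rng(3).uniform(-10, 10, (5, 2, 50)), fs=FS)
        out, report = reject_artifacts(ep, 75.0)
        assert report.n_dropped == 0
        assert report.n_kept + report.n_dropped == report.n_total == 5

    def test_rejection_is_idempotent(self):
        out1, _ = reject_artifacts(self.make_eps(), 75.0)
        out2, report2 = reject_artifacts(out1, 75.0)
        assert report2.n_dropped == 0
        assert np.array_equal(out1.data, out2.data)

    def test_trial_order_equivariance(self):
        ep = self.make_eps()
        perm = [2, 0, 1]
        ep_perm = EpochSet(ep.data[perm], fs=FS, labels=np.asarray(ep.labels)[perm])
        out, _ = reject_artifacts(ep, 75.0)
        out_perm, _ = reject_artifacts(ep_perm, 75.0)
        assert sorted(map(str, out.labels)) == sorted(map(str, out_perm.labels))


class TestWindowGrid:
    def test_canonical_grid_63_windows_of_25_samples(self):
        ep = EpochSet(np.zeros((1, 1, 1575)), fs=FS, origin_ms=-650.0)
        grid = partition_windows(ep, 50.0)
        assert (grid.n_windows, grid.samples_per_window) == (63, 25)
        assert grid.bounds(1) == (0, 25)  # samples 1-25, 1-based
        assert grid.window_times_ms(1) == (-650.0, -600.0)
        assert grid.bounds(63) == (1550, 1575)

    def test_windows_partition_the_epoch(self):
        grid = partition_windows(1575, 50.0, fs=FS, origin_ms=-650.0)
        covered = []
        for w in range(1, grid.n_windows + 1):
            a, b = grid.bounds(w)
            covered.extend(range(a, b))
        assert covered == list(range(1575))  # disjoint union, in order

    def test_whole_epoch_as_single_window(self):
        grid = partition_windows(1575, 3150.0, fs=FS, origin_ms=-650.0)
        assert grid.n_windows == 1 and grid.samples_per_window == 1575

    def test_indivisible_width_rejected_with_suggestions(self):
        with pytest.raises(ValueError, match="valid widths"):
            partition_windows(1575, 100.0, fs=FS)

    def test_window_range_slice(self):
        grid = partition_windows(1575, 50.0, fs=FS, origin_ms=-650.0)
        sl = grid.range_slice(14, 25)
        assert (sl.start, sl.stop) == (13 * 25, 25 * 25)
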