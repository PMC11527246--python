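"""Preprocessing chain: artifact windows, interpolation, resampling,
filtering, re-referencing, rejection, epoching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from esgpipe import preprocess as pre
from esgpipe.io_montage import ChannelInfo, Recording, builtin_montage


def _flat_grid_recording(fs=1000.0, n_sec=60, n_events=30, seed=0):
    mont = builtin_montage("cervical")
    rng = np.random.default_rng(seed)
    n = int(n_sec * fs)
    data = np.zeros((17, n))
    events = np.linspace(2 * fs, n - 2 * fs, n_events).astype(int)
    rec = Recording(data, fs, mont.channel_infos(),
                    reference="TH6",
                    events=[(int(e), "Stimulus/S  1") for e in events])
    return mont, rec, events


def _plant_square(rec, events, start_ms, end_ms, amp=400.0):
    w0 = int(round(start_ms * rec.fs / 1000.0))
    w1 = int(round(end_ms * rec.fs / 1000.0))
    for ev in events:
        rec.data[:, ev + w0: ev + w1 + 1] += amp


class TestArtifactWindowDetection:
    def test_planted_square_transient_is_contained_within_one_sample(self):
        mont, rec, events = _flat_grid_recording()
        _plant_square(rec, events, -2.0, 4.0)
        rec.data += 1e-3 * np.random.default_rng(1).standard_normal(
            rec.data.shape)  # break exact-zero baseline SD
        w = pre.detect_stim_artifact_window(rec, events, mont.labels)
        assert w.start_ms <= -2.0 + 1.0 and w.end_ms >= 4.0 - 1.0
        assert not w.fallback

    def test_zero_artifact_returns_flagged_default_window(self):
        mont, rec, events = _flat_grid_recording()
        rec.data += np.random.default_rng(2).standard_normal(rec.data.shape)
        w = pre.detect_stim_artifact_window(rec, events, mont.labels)
        assert w.fallback
        assert (w.start_ms, w.end_ms) == (-1.0, 4.0)

    def test_windows_widen_with_planted_duration(self):
        widths = []
        for dur in (2.0, 6.0, 9.0):
            mont, rec, events = _flat_grid_recording()
            _plant_square(rec, events, -1.0, -1.0 + dur)
            rec.data += 1e-3 * np.random.default_rng(3).standard_normal(
                rec.data.shape)
            w = pre.detect_stim_artifact_window(rec, events, mont.labels)
            widths.append(w.end_ms - w.start_ms)
        assert widths[0] < widths[1] < widths[2]

    def test_too_few_events_rejected(self):
        mont, rec, events = _flat_grid_recording(n_events=5)
        with pytest.raises(ValueError):
            pre.detect_stim_artifact_window(rec, events, mont.labels)


class TestArtifactInterpolation:
    def test_linear_ramp_reproduced_exactly(self):
        rec = Recording(np.arange(2000.0)[None, :] * 0.5, 1000.0,
                        [ChannelInfo("A")])
        events = np.array([500, 1200])
        w = pre.ArtifactWindow(-2.0, 4.0)
        out = pre.interpolate_artifact(rec, events, w)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-9)

    def test_samples_outside_windows_untouched(self):
        rng = np.random.default_rng(4)
        rec = Recording(rng.standard_normal((3, 2000)), 1000.0,
                        [ChannelInfo(c) for c in "ABC"])
        events = np.array([500, 1200])
        w = pre.ArtifactWindow(-2.0, 4.0)
        out = pre.interpolate_artifact(rec, events, w)
        gap = np.zeros(2000, bool)
        for ev in events:
            gap[ev - 2: ev + 5] = True
        np.testing.assert_array_equal(out.data[:, ~gap], rec.data[:, ~gap])
        assert not np.array_equal(out.data[:, gap], rec.data[:, gap])

    def test_monotone_context_yields_monotone_gap(self):
        """Shape preservation: across a gap flanked by increasing context,
        the interpolant must not overshoot (PCHIP property)."""
        x = np.concatenate([np.linspace(0, 1, 500) ** 2,
                            2 + np.linspace(0, 1, 1500) ** 0.5])
        rec = Recording(x[None, :], 1000.0, [ChannelInfo("A")])
        events = np.array([500])
        w = pre.ArtifactWindow(-3.0, 3.0)
        out = pre.interpolate_artifact(rec, events, w)
        gap = out.data[0, 495:508]
        assert (np.diff(gap) >= -1e-12).all()
        assert gap.min() >= x[492] - 1e-9 and gap.max() <= x[510] + 1e-9

    def test_overlapping_windows_rejected(self):
        rec = Recording(np.zeros((1, 2000)), 1000.0, [ChannelInfo("A")])
        with pytest.raises(ValueError):
            pre.interpolate_artifact(rec, np.array([500, 505]),
                                     pre.ArtifactWindow(-2.0, 4.0))


class TestResampling:
    def test_sinusoid_amplitude_preserved_within_1pct(self):
        fs = 10000.0
        t = np.arange(int(3 * fs)) / fs
        rec = Recording(np.sin(2 * np.pi * 100 * t)[None, :], fs,
                        [ChannelInfo("A")])
        out = pre.resample(rec, 1000.0)
        seg = out.data[0, 500:2500]
        assert abs(np.sqrt(2 * np.mean(seg**2)) - 1.0) < 0.01

    def test_event_indices_rescaled(self):
        rec = Recording(np.zeros((1, 30000)), 10000.0, [ChannelInfo("A")],
                        events=[(10000, "Stimulus/S  1")])
        out = pre.resample(rec, 1000.0)
        assert out.events[0][0] == 1000
        assert out.fs == 1000.0

    def test_above_nyquist_content_suppressed(self):
        """A 600 Hz tone must not alias into the 1 kHz output."""
        fs = 10000.0
        t = np.arange(int(3 * fs)) / fs
        rec = Recording(np.sin(2 * np.pi * 600 * t)[None, :], fs,
                        [ChannelInfo("A")])
        out = pre.resample(rec, 1000.0)
        assert np.sqrt(np.mean(out.data[0, 500:2500] ** 2)) < 0.01

    def test_invalid_target_rejected(self):
        rec = Recording(np.zeros((1, 100)), 1000.0, [ChannelInfo("A")])
        with pytest.raises(ValueError):
            pre.resample(rec, 0.0)


class TestZeroPhaseFilter:
    def _tone(self, f, fs=1000.0, n_sec=20):
        t = np.arange(int(n_sec * fs)) / fs
        return Recording(np.sin(2 * np.pi * f * t)[None, :], fs,
                         [ChannelInfo("A")])

    def test_passband_tone_unchanged_with_zero_lag(self):
        rec = self._tone(100.0)
        out = pre.filter_zero_phase(rec, band=(30, 400), notch=None)
        seg = slice(5000, 15000)
        amp = np.sqrt(2 * np.mean(out.data[0, seg] ** 2))
        assert abs(amp - 1.0) < 0.01
        xc = np.correlate(out.data[0, seg], rec.data[0, seg], "full")
        lag = xc.argmax() - (seg.stop - seg.start - 1)
        assert abs(lag) * 1000.0 / rec.fs < 0.1

    def test_band_edge_gain_is_half_after_two_passes(self):
        """|H|² at the Butterworth cutoff = (1/√2)² = 0.5."""
        rec = self._tone(30.0)
        out = pre.filter_zero_phase(rec, band=(30, 400), notch=None)
        amp = np.sqrt(2 * np.mean(out.data[0, 5000:15000] ** 2))
        assert abs(amp - 0.5) < 0.02

    def test_dc_offset_rejected(self):
        rec = Recording(np.full((1, 20000), 10.0), 1000.0, [ChannelInfo("A")])
        out = pre.filter_zero_phase(rec, band=(30, 400), notch=None)
        assert abs(out.data[0, 5000:15000].mean()) < 0.01

    def test_notch_removes_50hz(self):
        rec = self._tone(50.0)
        out = pre.filter_zero_phase(rec, band=None, notch=(48, 53))
        assert np.sqrt(2 * np.mean(out.data[0, 5000:15000] ** 2)) < 0.01

    def test_comb_attenuates_harmonics(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = sum(np.sin(2 * np.pi * 50 * h * t) for h in (1, 2, 3))
        rec = Recording(x[None, :], fs, [ChannelInfo("A")])
        out = pre.filter_zero_phase(rec, band=None, notch=None, comb=(50.0, 3))
        assert np.sqrt(np.mean(out.data[0, 5000:15000] ** 2)) < 0.05 * np.sqrt(
            np.mean(x[5000:15000] ** 2))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(a=hst.floats(-3, 3), b=hst.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        def filt(sig):
            rec = Recording(sig[None, :], 1000.0, [ChannelInfo("A")])
            return pre.filter_zero_phase(rec, band=(30, 400),
                                         notch=None).data[0]
        lhs = filt(a * x + b * y)
        rhs = a * filt(x) + b * filt(y)
        assert np.max(np.abs(lhs - rhs)) <= 1e-6 * max(np.max(np.abs(lhs)), 1.0)


class TestRereference:
    def _two_channel(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((2, 1000))
        return Recording(data, 1000.0,
                         [ChannelInfo("A"), ChannelInfo("B")], reference="R")

    def test_involution_through_retained_original_reference(self):
        rec = self._two_channel()
        fwd = pre.rereference(rec, "A")
        assert "R" in fwd.labels
        back = pre.rereference(fwd, "R", keep_original=False)
        for lab in ("A", "B"):
            np.testing.assert_allclose(back.data[back.ch_index(lab)],
                                       rec.data[rec.ch_index(lab)],
                                       atol=1e-12)

    def test_average_reference_centres_every_sample(self):
        rec = self._two_channel()
        out = pre.rereference(rec, "average")
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_ventral_reference_boosts_target_amplitude_for_opposite_pole(self):
        """With the ventral channel carrying the dipole's opposite pole,
        re-referencing to it adds the two poles together."""
        t = np.arange(1000) / 1000.0
        wave = np.exp(-0.5 * ((t - 0.5) / 0.01) ** 2)
        data = np.vstack([-1.0 * wave, +0.5 * wave])  # dorsal target, ventral
        rec = Recording(data, 1000.0,
                        [ChannelInfo("SC6"), ChannelInfo("AC")],
                        reference="TH6")
        out = pre.rereference(rec, "AC", keep_original=False)
        assert np.abs(out.data[0]).max() > np.abs(rec.data[0]).max()


class TestRejection:
    def _esg_recording(self, data):
        chs = [ChannelInfo(f"E{i}", role="esg", patch="cervical")
               for i in range(data.shape[0])]
        return Recording(data, 1000.0, chs)

    def test_single_spike_masks_sample_but_keeps_channel(self):
        data = np.zeros((2, 1000))
        data[0, 500] = 150.0
        mask, dropped = pre.reject_timepoints(self._esg_recording(data))
        assert not dropped
        assert not mask[500] and mask.sum() == 999

    def test_majority_exceeding_channel_is_dropped_not_masked(self):
        data = np.zeros((2, 1000))
        data[0, :600] = 150.0
        mask, dropped = pre.reject_timepoints(self._esg_recording(data))
        assert dropped == ["E0"]
        assert mask.all()

    def test_clean_data_yields_full_mask(self):
        data = np.random.default_rng(7).standard_normal((3, 1000))
        mask, dropped = pre.reject_timepoints(self._esg_recording(data))
        assert mask.all() and not dropped

    def test_all_channels_dropped_is_an_error(self):
        data = np.full((2, 1000), 200.0)
        with pytest.raises(RuntimeError):
            pre.reject_timepoints(self._esg_recording(data))


class TestEpoching:
    def _recording(self, n=60000, n_ch=2, seed=8):
        rng = np.random.default_rng(seed)
        return Recording(rng.standard_normal((n_ch, n)), 1000.0,
                         [ChannelInfo(f"C{i}") for i in range(n_ch)])

    def test_inclusive_endpoints_give_901_samples(self):
        rec = self._recording()
        eps = pre.epoch_and_baseline(rec, np.array([1000, 2000]),
                                     (-200.0, 700.0), (-110.0, -10.0))
        assert eps.data.shape[2] == 901
        assert eps.times_ms[0] == -200.0 and eps.times_ms[-1] == 700.0

    def test_baseline_mean_is_zero_per_trial_and_channel(self):
        rec = self._recording()
        eps = pre.epoch_and_baseline(rec, np.arange(1000, 50000, 1000),
                                     (-200.0, 700.0), (-110.0, -10.0))
        b0, b1 = eps.time_index(-110.0), eps.time_index(-10.0)
        base = eps.data[:, :, b0: b1 + 1].mean(axis=2)
        assert np.abs(base).max() < 1e-9

    def test_retention_matches_direct_mask_evaluation(self):
        rec = self._recording()
        events = np.arange(1000, 50000, 1000)
        rng = np.random.default_rng(9)
        mask = np.ones(rec.n_samples, bool)
        mask[rng.choice(rec.n_samples, size=40, replace=False)] = False
        eps = pre.epoch_and_baseline(rec, events, (-200.0, 700.0),
                                     (-110.0, -10.0), mask=mask)
        expected = np.array([mask[e - 200: e + 701].all() for e in events])
        np.testing.assert_array_equal(eps.retained, expected)
        assert eps.retained.sum() < len(events)  # some trials overlap masks

    def test_window_outside_recording_rejected(self):
        rec = self._recording(n=1000)
        with pytest.raises(ValueError):
            pre.epoch_and_baseline(rec, np.array([100]), (-200.0, 700.0),
                                   (-110.0, -10.0))

    def test_baseline_must_lie_inside_window(self):
        rec = self._recording()
        with pytest.raises(ValueError):
            pre.epoch_and_baseline(rec, np.array([5000]), (-200.0, 700.0),
                                   (-300.0, -10.0))
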