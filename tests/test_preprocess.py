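"""Filtering, channel/trial rejection, HFC, and artifact removal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import opmpipe as op
from opmpipe import preprocess, synth
from opmpipe.data import Recording
from opmpipe.exceptions import (DegenerateArrayError, EmptySetError,
                                FilterDesignError)

FS = 375.0


def _tone_recording(array, freqs_amps, duration=20.0):
    t = np.arange(int(duration * FS)) / FS
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(x, (array.n_channels, 1))
    return Recording(data=data, sampling_rate=FS, array=array)


def _trim(x, seconds=2.0):
    k = int(seconds * FS)
    return x[..., k:-k]


class TestNotchFilter:
    def test_powerline_tone_removed(self, small_array):
        rec = _tone_recording(small_array, [(50.0, 1.0)])
        out = preprocess.notch_filter(rec)
        assert np.sqrt(np.mean(_trim(out.data[0]) ** 2)) < 0.03 * np.sqrt(0.5)

    def test_passband_tone_preserved(self, small_array):
        rec = _tone_recording(small_array, [(20.0, 1.0)])
        out = preprocess.notch_filter(rec)
        ratio = np.sqrt(np.mean(_trim(out.data[0]) ** 2) / np.mean(_trim(rec.data[0]) ** 2))
        assert abs(ratio - 1.0) < 0.01

    def test_zero_in_zero_out(self, small_array):
        rec = _tone_recording(small_array, [(50.0, 0.0)])
        assert np.allclose(preprocess.notch_filter(rec).data, 0.0)

    def test_frequency_above_nyquist_rejected(self, small_array):
        rec = _tone_recording(small_array, [(20.0, 1.0)], duration=2.0)
        with pytest.raises(FilterDesignError):
            preprocess.notch_filter(rec, freqs=(200.0,))


class TestBandpassFilter:
    def test_dc_removed(self, small_array):
        rec = _tone_recording(small_array, [(20.0, 0.0)])
        rec.data += 5.0
        out = preprocess.bandpass_filter(rec, 1.0, 150.0)
        assert np.abs(_trim(out.data).mean()) < 1e-3 * 5.0

    @pytest.mark.parametrize("band,freq,keep", [
        ((1, 150), 10.0, True),
        ((13, 30), 20.0, True),
        ((13, 30), 50.0, False),
    ])
    def test_tone_transfer(self, small_array, band, freq, keep):
        rec = _tone_recording(small_array, [(freq, 1.0)])
        out = preprocess.bandpass_filter(rec, *band)
        ratio = np.sqrt(np.mean(_trim(out.data[0]) ** 2) / np.mean(_trim(rec.data[0]) ** 2))
        if keep:
            assert abs(ratio - 1.0) < 0.02
        else:
            assert ratio < 10 ** (-20 / 20)

    def test_invalid_band_rejected(self, small_array):
        rec = _tone_recording(small_array, [(20.0, 1.0)], duration=2.0)
        with pytest.raises(FilterDesignError):
            preprocess.bandpass_filter(rec, 30.0, 13.0)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        lhs = preprocess.bandpass_array(a * x + b * y, FS, 1, 150)
        rhs = (a * preprocess.bandpass_array(x, FS, 1, 150)
               + b * preprocess.bandpass_array(y, FS, 1, 150))
        assert np.allclose(lhs, rhs, atol=1e-10 * max(1.0, abs(a) + abs(b)))


class TestBadChannels:
    def test_dead_and_noisy_channels_flagged(self, small_array):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((small_array.n_channels, int(20 * FS)))
        data[3] = 0.0
        data[7] *= 20.0
        rec = Recording(data=data, sampling_rate=FS, array=small_array)
        mask = preprocess.detect_bad_channels(rec)
        assert mask[3] and mask[7]
        assert mask.sum() == 2

    def test_homogeneous_channels_untouched(self, small_array):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((small_array.n_channels, int(20 * FS)))
        rec = Recording(data=data, sampling_rate=FS, array=small_array)
        assert preprocess.detect_bad_channels(rec).sum() == 0


class TestHFC:
    def test_uniform_field_annihilated(self, small_array):
        b = np.array([1.0, -2.0, 0.5])
        reading = small_array.channel_orientations @ b
        data = np.outer(reading, np.sin(np.linspace(0, 20, 1000)))
        rec = Recording(data=data, sampling_rate=FS, array=small_array)
        out, M = preprocess.homogeneous_field_correction(rec)
        assert np.abs(out.data).max() < 1e-10 * np.abs(data).max()

    def test_projector_idempotent_and_rank(self, small_array):
        M = preprocess.hfc_projector(small_array.channel_orientations)
        assert np.abs(M @ M - M).max() < 1e-12
        assert np.linalg.matrix_rank(np.eye(M.shape[0]) - M) == 3

    def test_dipolar_signal_survives_interference(self, truth):
        """10x uniform interference removed; the dipolar signal loses <5% RMS
        (its own spatially uniform component is all the projector can take).
        Uses the full 64-sensor array: sparser caps alias more of a dipole
        into the uniform subspace."""
        from opmpipe.forward import dipole_field, tangential_basis
        array = op.make_sensor_array(64, seed=0)
        rng = np.random.default_rng(4)
        t1, _, _ = tangential_basis(truth.motor_location, array.sphere_origin)
        g = dipole_field(truth.motor_location, t1, array)
        g /= np.abs(g).max()
        D = np.outer(g, synth.bandlimited_noise(4000, FS, 13, 30, rng))
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        uni = 10.0 * np.outer(array.channel_orientations @ d,
                              synth.pink_noise(4000, rng))
        rec = Recording(data=D + uni, sampling_rate=FS, array=array)
        out, _ = preprocess.homogeneous_field_correction(rec)
        resid = out.data - D
        assert np.sqrt((resid ** 2).mean()) < 0.05 * np.sqrt((D ** 2).mean())

    def test_degenerate_orientations_rejected(self):
        N = np.tile(np.array([[0.0, 0.0, 1.0]]), (10, 1))
        with pytest.raises(DegenerateArrayError):
            preprocess.hfc_projector(N)


class TestSegmentation:
    def test_sixty_events_give_1875_sample_trials(self, visuomotor_run):
        rec, motion = visuomotor_run
        ts = preprocess.segment_trials(rec, motion.offset_times, (-1.0, 4.0))
        assert ts.n_samples == 1875
        assert ts.n_trials >= 59  # the last event may not fit the window
        assert np.allclose(ts.times[0], -1.0)

    def test_edge_events_dropped_and_empty_errors(self, small_array):
        rng = np.random.default_rng(0)
        rec = Recording(data=rng.standard_normal((small_array.n_channels, int(10 * FS))),
                        sampling_rate=FS, array=small_array)
        ts = preprocess.segment_trials(rec, [0.5, 3.0], (-1.0, 4.0))
        assert ts.n_trials == 1  # the 0.5-s event starts before the recording
        with pytest.raises(EmptySetError):
            preprocess.segment_trials(rec, [], (-1.0, 4.0))
        with pytest.raises(EmptySetError):
            preprocess.segment_trials(rec, [0.5], (-1.0, 40.0))


class TestTrialRejection:
    def _trials(self, array, n=10, seed=0):
        rng = np.random.default_rng(seed)
        from opmpipe.data import TrialSet
        data = rng.standard_normal((n, array.n_channels, 750))
        return TrialSet(data=data, sampling_rate=FS, array=array, window=(-1, 1))

    def test_identical_trials_none_flagged(self, small_array):
        from opmpipe.data import TrialSet
        one = np.random.default_rng(0).standard_normal((1, small_array.n_channels, 750))
        ts = TrialSet(data=np.repeat(one, 10, axis=0), sampling_rate=FS,
                      array=small_array, window=(-1, 1))
        assert preprocess.reject_bad_trials(ts).bad_trials.sum() == 0

    def test_single_outlier_trial_flagged(self, small_array):
        # deterministic construction: sinusoidal trials with a small linear
        # amplitude spread, one trial at 4x amplitude on one channel.  A lone
        # outlier inflates the across-trial mean and std of variance itself,
        # so it is only flaggable at all for more than ~10 trials.
        from opmpipe.data import TrialSet
        n = 20
        t = np.arange(750) / FS
        base = np.sin(2 * np.pi * 10 * t)
        amps = 1.0 + 0.005 * np.arange(n)
        data = np.tile(base, (n, small_array.n_channels, 1)) * amps[:, None, None]
        data[4, 7] *= 4.0
        ts = TrialSet(data=data, sampling_rate=FS, array=small_array, window=(-1, 1))
        out = preprocess.reject_bad_trials(ts)
        assert out.bad_trials[4]
        assert out.bad_trials.sum() == 1
        # input mask untouched (no in-place modification)
        assert ts.bad_trials.sum() == 0

    def test_mask_invariant_to_channel_rescaling(self, small_array):
        ts = self._trials(small_array, seed=3)
        ts.data[2, 5] *= 5.0
        m1 = preprocess.reject_bad_trials(ts).bad_trials
        ts2 = self._trials(small_array, seed=3)
        ts2.data[2, 5] *= 5.0
        ts2.data *= 7.5  # common rescaling of every trial
        m2 = preprocess.reject_bad_trials(ts2).bad_trials
        assert np.array_equal(m1, m2)


class TestSegmentRejection:
    def test_segment_count_and_noise_flagging(self, small_array, truth):
        rec = synth.simulate_resting_dataset(small_array, truth, duration=60.0, seed=1)
        segs, mask = preprocess.reject_bad_segments(rec, 10.0)
        assert segs.n_trials == 6
        assert mask.sum() == 0  # clean simulation
        # a single outlier segment is only flaggable among > 10 segments
        # (it inflates its own mean + 3 std threshold below that)
        rec15 = synth.simulate_resting_dataset(small_array, truth, duration=150.0,
                                               seed=1)
        rng = np.random.default_rng(8)
        noise = 10 * rec15.data.std() * rng.standard_normal((rec15.n_channels, 3750))
        rec15.data[:, 7500:11250] += noise   # broadband noise into segment 2
        _, mask2 = preprocess.reject_bad_segments(rec15, 10.0)
        assert mask2[2]
        assert mask2.sum() == 1


class TestArtifactRemoval:
    def test_no_reference_is_identity(self, small_array, truth):
        rec = synth.simulate_resting_dataset(small_array, truth, duration=30.0, seed=2)
        with pytest.warns(UserWarning):
            out = preprocess.remove_stereotyped_artifacts(rec, references=None)
        assert np.array_equal(out.data, rec.data)

    def test_planted_cardiac_component_removed(self, small_array, truth):
        ecg = synth.cardiac_trace(130.0, seed=9)
        rec = synth.simulate_resting_dataset(small_array, truth, duration=130.0,
                                             seed=3, artifact_traces={"ecg": ecg})

        def corr(rec_):
            x = rec_.data - rec_.data.mean(axis=1, keepdims=True)
            e = ecg - ecg.mean()
            c = x @ e / (np.linalg.norm(x, axis=1) * np.linalg.norm(e))
            return np.abs(c).max()

        before = corr(rec)
        out = preprocess.remove_stereotyped_artifacts(rec, {"ecg": ecg}, seed=0)
        assert before > 0.5  # the artifact really dominates some channels
        assert corr(out) < 0.1 * before

    def test_rank_deficient_data_handled(self, small_array):
        rng = np.random.default_rng(5)
        half = rng.standard_normal((small_array.n_channels // 2, int(125 * FS // 1)))
        data = np.vstack([half, half])  # duplicated channels
        rec = Recording(data=data, sampling_rate=FS, array=small_array)
        ref = rng.standard_normal(data.shape[1])
        out = preprocess.remove_stereotyped_artifacts(rec, {"x": ref}, seed=0)
        assert out.data.shape == data.shape
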