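import numpy as np
import pandas as pd
import pytest

from hgamap import (ContinuousRecording, DataError, EventTimeline,
                    ParadigmSpec, bandpass_hga, build_timeline,
                    common_average_reference, envelope_downsample,
                    epoch_log_bandpower, extract_trial_samples, preprocess,
                    remove_drift, zscore_to_rest)
from hgamap.sigproc import EnvelopePower

FS = 1200.0


def tone(freq, amplitude=1.0, duration=10.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def rec_of(*channels, fs=FS, excluded=()):
    data = np.vstack(channels)
    names = [f"c{i}" for i in range(data.shape[0])]
    return ContinuousRecording(data=data, fs=fs, channel_names=names,
                               excluded=frozenset(excluded))


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def mid(x, frac=0.6):
    k = int(len(x) * (1 - frac) / 2)
    return x[k: len(x) - k]


def butter4_gain(f, cutoff, kind):
    """Analytic two-pass (zero-phase) order-4 Butterworth magnitude."""
    ratio = (cutoff / f) if kind == "highpass" else (f / cutoff)
    single = 1.0 / np.sqrt(1.0 + ratio ** 8)
    return single ** 2


class TestRecordingValidation:
    def test_low_sampling_rate_rejected(self):
        with pytest.raises(DataError):
            rec_of(np.zeros(1000), fs=1000.0)

    def test_rate_not_divisible_by_envelope_rate_rejected(self):
        with pytest.raises(DataError):
            rec_of(np.zeros(1300), fs=1300.0)


class TestRemoveDrift:
    def test_constant_channel_removed(self):
        out = remove_drift(rec_of(np.full(12000, 40.0)))
        assert np.max(np.abs(out.data)) < 1e-6 * 40.0

    def test_slow_drift_attenuated_below_5_percent(self):
        x = tone(0.2, duration=30.0)
        out = remove_drift(rec_of(x))
        assert rms(mid(out.data[0])) < 0.05 * rms(mid(x))

    def test_passband_tone_preserved_within_1_percent(self):
        x = tone(100.0)
        out = remove_drift(rec_of(x))
        assert rms(mid(out.data[0])) == pytest.approx(rms(mid(x)), rel=0.01)

    def test_nonfinite_input_rejected(self):
        x = np.zeros(2400)
        x[5] = np.nan
        with pytest.raises(DataError):
            remove_drift(rec_of(x))


class TestCommonAverage:
    def test_identical_channels_become_zero(self):
        x = tone(10.0)
        out = common_average_reference(rec_of(x, x.copy(), x.copy()))
        assert np.max(np.abs(out.data)) < 1e-12

    def test_two_channels_give_half_difference(self, rng):
        a, b = rng.normal(size=(2, 2400))
        out = common_average_reference(rec_of(a, b))
        assert np.allclose(out.data[0], (a - b) / 2)
        assert np.allclose(out.data[1], (b - a) / 2)

    def test_included_mean_is_zero_and_excluded_untouched(self, rng):
        chans = rng.normal(size=(4, 2400))
        out = common_average_reference(
            rec_of(*chans, excluded=(3,)))
        inc = out.data[:3]
        assert np.max(np.abs(inc.mean(axis=0))) < 1e-12
        assert np.array_equal(out.data[3], chans[3])

    def test_fewer_than_two_included_rejected(self, rng):
        chans = rng.normal(size=(2, 2400))
        with pytest.raises(DataError):
            common_average_reference(rec_of(*chans, excluded=(1,)))


class TestBandpass:
    @pytest.mark.parametrize("freq,check", [
        (100.0, "analytic"),   # in-band: must match the analytic cascade
        (10.0, "min40db"),     # far below band
        (300.0, "min15db"),    # above band at fs 1200
    ])
    def test_cascade_magnitude(self, freq, check):
        x = tone(freq)
        out = bandpass_hga(rec_of(x))
        ratio = rms(mid(out.data[0])) / rms(mid(x))
        if check == "analytic":
            # the bilinear design deviates from the analog-prototype formula
            # by <1% at these frequencies
            expected = (butter4_gain(freq, 60.0, "highpass")
                        * butter4_gain(freq, 170.0, "lowpass"))
            assert ratio == pytest.approx(expected, rel=0.01)
        elif check == "min40db":
            assert 20 * np.log10(ratio) <= -40
        else:
            assert 20 * np.log10(ratio) <= -15


class TestEnvelope:
    def test_tone_envelope_equals_amplitude(self):
        env = envelope_downsample(rec_of(tone(100.0, amplitude=3.0)))
        assert np.allclose(mid(env[0]), 3.0, rtol=0.03)

    def test_zero_signal_gives_zero_envelope(self):
        env = envelope_downsample(rec_of(np.zeros(2400)))
        assert np.all(env == 0)

    def test_output_length(self):
        env = envelope_downsample(rec_of(np.zeros(2405)))
        assert env.shape[1] == 2405 // 3  # fs/400 = 3 at 1200 Hz


class TestEpochLogPower:
    def test_constant_envelope(self):
        env = np.full((1, 400), 2.5)
        p = epoch_log_bandpower(env, ["c0"])
        assert p.n_epochs == 10
        assert np.allclose(p.log_power, np.log(2.5 ** 2))

    def test_250_s_envelope_gives_2500_epochs(self):
        env = np.ones((1, int(250 * 400)))
        assert epoch_log_bandpower(env, ["c0"]).n_epochs == 2500

    def test_alternating_amplitude_runs(self):
        # 0.5 s at amplitude 1, 0.5 s at amplitude 2, repeated
        block = np.concatenate([np.ones(200), np.full(200, 2.0)])
        env = np.tile(block, 3)[None, :]
        p = epoch_log_bandpower(env, ["c0"])
        expected = np.tile(np.r_[np.zeros(5), np.full(5, np.log(4.0))], 3)
        assert np.allclose(p.log_power[0], expected)

    def test_zero_power_epoch_rejected_with_location(self):
        env = np.ones((1, 400))
        env[0, 40:80] = 0.0
        with pytest.raises(DataError, match="epoch 1"):
            epoch_log_bandpower(env, ["c0"])


def toy_timeline(rest_onset, rest_duration, session_s):
    ev = pd.DataFrame(
        [[rest_onset, rest_duration, "rest", 1, pd.NA]],
        columns=["onset_s", "duration_s", "label", "block", "trial"])
    ev["block"] = ev["block"].astype("Int64")
    ev["trial"] = ev["trial"].astype("Int64")
    return EventTimeline(events=ev, session_s=session_s)


class TestZScore:
    def test_hand_computed_example(self):
        # rest log-powers {1, 3}: mean 2, sample SD sqrt(2); z(4) = sqrt(2)
        power = EnvelopePower(log_power=np.array([[1.0, 3.0, 4.0]]),
                              epoch_start_times=np.array([0.0, 0.1, 0.2]),
                              channel_names=["c0"])
        z = zscore_to_rest(power, toy_timeline(0.0, 0.2, 0.3))
        assert z.z[0, 2] == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-9)
        assert z.z[0, 0] == pytest.approx(-1.0 / np.sqrt(2.0), abs=1e-9)

    def test_epoch_at_baseline_mean_maps_to_zero(self):
        power = EnvelopePower(log_power=np.array([[1.0, 3.0, 2.0]]),
                              epoch_start_times=np.array([0.0, 0.1, 0.2]),
                              channel_names=["c0"])
        z = zscore_to_rest(power, toy_timeline(0.0, 0.2, 0.3))
        assert z.z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_pooled_rest_z_standardized(self, default_session):
        z = default_session.z
        rest = z.z[:, z.rest_epochs]
        assert np.max(np.abs(rest.mean(axis=1))) < 1e-9
        assert np.max(np.abs(rest.std(axis=1, ddof=1) - 1)) < 1e-9

    def test_constant_rest_rejected(self):
        power = EnvelopePower(log_power=np.array([[2.0, 2.0, 5.0]]),
                              epoch_start_times=np.array([0.0, 0.1, 0.2]),
                              channel_names=["c0"])
        with pytest.raises(DataError, match="c0"):
            zscore_to_rest(power, toy_timeline(0.0, 0.2, 0.3))


class TestChainProperties:
    def test_scaling_shifts_log_power_and_leaves_z_invariant(self, rng):
        spec = ParadigmSpec(pre_rest_s=1.0, n_blocks=2, rest_s=2.4,
                            trials_per_block=2)
        tl = build_timeline(spec)
        n = int(spec.session_s * FS)
        base = rng.normal(size=(3, n))
        k = 3.0
        chains = []
        for scale in (1.0, k):
            rec = rec_of(*(scale * base))
            rec = remove_drift(rec)
            rec = common_average_reference(rec)
            rec = bandpass_hga(rec)
            env = envelope_downsample(rec)
            power = epoch_log_bandpower(env, rec.channel_names)
            chains.append((power, zscore_to_rest(power, tl)))
        (p1, z1), (pk, zk) = chains
        assert np.allclose(pk.log_power - p1.log_power, 2 * np.log(k),
                           atol=1e-9)
        assert np.allclose(zk.z, z1.z, atol=1e-9)

    def test_trial_matrix_shape_and_planted_window(self, default_session):
        trials = default_session.trials
        assert trials.hga.shape == (16, 10, 10)
        # plant z = 1 exactly on one trial's window; all other samples 0
        z = default_session.z
        z0 = z.z.copy()
        try:
            z.z = np.zeros_like(z.z)
            cue = default_session.timeline.close_cues().iloc[12]
            start = int(round(cue["onset_s"] * 10)) + 4
            z.z[2, start: start + 6] = 1.0
            t = extract_trial_samples(z, default_session.timeline)
            b, k = int(cue["block"]) - 1, int(cue["trial"]) - 1
            assert t.hga[2, b, k] == pytest.approx(1.0)
            assert t.hga.sum() == pytest.approx(1.0)
        finally:
            z.z = z0

    def test_missing_cues_rejected(self, default_session):
        tl = toy_timeline(0.0, 12.0, 250.0)
        with pytest.raises(DataError):
            extract_trial_samples(default_session.z, tl)

    def test_end_to_end_sensitivity_on_responsive_channels(self,
                                                           default_session):
        # responsive channels: window-mean z well above rest; others near 0
        truth = default_session.truth
        mean_hga = default_session.trials.hga.mean(axis=(1, 2))
        assert np.all(mean_hga[truth.responsive] > 0.2)
        assert np.all(np.abs(mean_hga[~truth.responsive]) < 0.2)
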