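"""High-gamma signal chain: continuous ECoG -> rest-standardized HGA scores.

The stage order is fixed: drift removal (2 Hz high-pass, 4th-order
Butterworth) -> common average reference -> 60-170 Hz band-pass (cascade of
4th-order high- and low-pass) -> Hilbert envelope -> downsample to 400 Hz ->
100-ms log band-power epochs -> z-score against the pooled 12-s rest phases.
All filtering is zero-phase (forward-backward), so each Butterworth pass acts
twice on the magnitude response but response latencies are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError
from .paradigm import (EPOCH_S, EventTimeline, evaluation_window)

#: Envelope rate after downsampling (Hz).
ENVELOPE_FS = 400.0

#: High-gamma band edges (Hz).
HGA_BAND = (60.0, 170.0)

#: Drift-removal high-pass cutoff (Hz) and Butterworth order used throughout.
DRIFT_CUTOFF_HZ = 2.0
FILTER_ORDER = 4

#: Samples per 100-ms epoch at the envelope rate.
SAMPLES_PER_EPOCH = int(round(EPOCH_S * ENVELOPE_FS))


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal in microvolts.

    ``excluded`` channels (ground/bad) are carried through every stage
    untouched and never enter the common average or any statistic.
    """

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: Sequence[str]
    excluded: frozenset = frozenset()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("recording data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length does not match data rows")
        if self.fs < 1200:
            raise DataError(f"sampling rate {self.fs} Hz is below the 1200-Hz "
                            "acquisition floor")
        if abs(self.fs / ENVELOPE_FS - round(self.fs / ENVELOPE_FS)) > 1e-9:
            raise DataError(f"sampling rate {self.fs} Hz is not divisible by "
                            f"{ENVELOPE_FS:g} Hz")
        self.excluded = frozenset(int(i) for i in self.excluded)
        bad = [i for i in self.excluded if not 0 <= i < self.data.shape[0]]
        if bad:
            raise DataError(f"excluded channel indices out of range: {bad}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def included(self) -> np.ndarray:
        return np.array([i for i in range(self.n_channels)
                         if i not in self.excluded], dtype=int)


@dataclass
class EnvelopePower:
    """Log band power per channel in contiguous 100-ms epochs."""

    log_power: np.ndarray  # channels x epochs
    epoch_start_times: np.ndarray
    channel_names: Sequence[str]
    excluded: frozenset = frozenset()
    epoch_s: float = EPOCH_S

    @property
    def n_epochs(self) -> int:
        return self.log_power.shape[1]


@dataclass
class ZScoredHGA:
    """HGA standardized to the rest baseline, per channel and epoch."""

    z: np.ndarray  # channels x epochs
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    epoch_start_times: np.ndarray
    channel_names: Sequence[str]
    excluded: frozenset = frozenset()
    rest_epochs: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_epochs(self) -> int:
        return self.z.shape[1]

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]


@dataclass
class TrialSampleMatrix:
    """One window-mean HGA score per (electrode, block, trial).

    ``window_z`` keeps the six per-epoch z values inside each 0.4-1.0 s
    evaluation window for temporal-dynamics summaries.
    """

    hga: np.ndarray  # electrodes x blocks x trials
    window_z: np.ndarray  # electrodes x blocks x trials x 6
    channel_names: Sequence[str]
    excluded: frozenset = frozenset()

    @property
    def n_blocks(self) -> int:
        return self.hga.shape[1]

    @property
    def trials_per_block(self) -> int:
        return self.hga.shape[2]


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise DataError(f"{what} contains non-finite values")


def remove_drift(rec: ContinuousRecording) -> ContinuousRecording:
    """Zero-phase 2 Hz high-pass (Butterworth, order 4) on every channel."""
    _check_finite(rec.data, "recording")
    sos = sps.butter(FILTER_ORDER, DRIFT_CUTOFF_HZ, btype="highpass",
                     fs=rec.fs, output="sos")
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=-1))


def common_average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean over included channels from each of them.

    Excluded (ground/bad) channels pass through untouched.
    """
    inc = rec.included
    if len(inc) < 2:
        raise DataError(f"common average needs >= 2 included channels, "
                        f"have {len(inc)}")
    out = rec.data.copy()
    out[inc] -= rec.data[inc].mean(axis=0, keepdims=True)
    return replace(rec, data=out)


def bandpass_hga(rec: ContinuousRecording) -> ContinuousRecording:
    """60-170 Hz band-pass: cascaded order-4 high- and low-pass, zero-phase."""
    lo, hi = HGA_BAND
    if rec.fs <= 2 * hi:
        raise ConfigError(f"band edge {hi} Hz requires fs > {2 * hi} Hz, "
                          f"got {rec.fs}")
    sos_hp = sps.butter(FILTER_ORDER, lo, btype="highpass", fs=rec.fs,
                        output="sos")
    sos_lp = sps.butter(FILTER_ORDER, hi, btype="lowpass", fs=rec.fs,
                        output="sos")
    y = sps.sosfiltfilt(sos_hp, rec.data, axis=-1)
    y = sps.sosfiltfilt(sos_lp, y, axis=-1)
    return replace(rec, data=y)


def envelope_downsample(rec: ContinuousRecording) -> np.ndarray:
    """Hilbert-envelope magnitude at the native rate, reduced to 400 Hz.

    Reduction averages consecutive non-overlapping groups of ``fs/400``
    samples, which doubles as an anti-alias step for the nonnegative
    envelope.  Returns a channels x samples array at 400 Hz.
    """
    factor = rec.fs / ENVELOPE_FS
    if abs(factor - round(factor)) > 1e-9:
        raise DataError(f"fs {rec.fs} not divisible by {ENVELOPE_FS:g}")
    factor = int(round(factor))
    env = np.abs(sps.hilbert(rec.data, axis=-1))
    n_out = rec.n_samples // factor
    env = env[:, : n_out * factor].reshape(rec.n_channels, n_out, factor)
    return env.mean(axis=-1)


def epoch_log_bandpower(envelope: np.ndarray,
                        channel_names: Sequence[str],
                        excluded: frozenset = frozenset()) -> EnvelopePower:
    """Mean squared envelope per 100-ms epoch, natural-log transformed.

    A trailing partial epoch is dropped.  Zero power in any epoch of an
    included channel is an error (the log is undefined there).
    """
    envelope = np.asarray(envelope, dtype=float)
    n_ch, n = envelope.shape
    n_epochs = n // SAMPLES_PER_EPOCH
    if n_epochs == 0:
        raise DataError("envelope shorter than one 100-ms epoch")
    power = (envelope[:, : n_epochs * SAMPLES_PER_EPOCH] ** 2
             ).reshape(n_ch, n_epochs, SAMPLES_PER_EPOCH).mean(axis=-1)
    included = [i for i in range(n_ch) if i not in excluded]
    zero = np.argwhere(power[included] <= 0)
    if len(zero):
        ch, ep = zero[0]
        raise DataError(f"zero band power in channel "
                        f"'{channel_names[included[ch]]}', epoch {ep}: "
                        "log-power undefined")
    with np.errstate(divide="ignore"):
        log_power = np.log(power)
    times = np.arange(n_epochs) * EPOCH_S
    return EnvelopePower(log_power=log_power, epoch_start_times=times,
                         channel_names=list(channel_names), excluded=excluded)


def rest_epoch_indices(timeline: EventTimeline, n_epochs: int) -> np.ndarray:
    """0-based indices of epochs fully inside the numbered 12-s rest phases.

    The pre-task rest is excluded: the baseline is defined by the rest phase
    of each block only.
    """
    idx = []
    for _, row in timeline.rest_phases().iterrows():
        start = int(round(row["onset_s"] / EPOCH_S))
        count = int(np.floor(row["duration_s"] / EPOCH_S + 1e-9))
        stop = min(start + count, n_epochs)
        idx.extend(range(start, stop))
    return np.asarray(idx, dtype=int)


def zscore_to_rest(power: EnvelopePower, timeline: EventTimeline) -> ZScoredHGA:
    """Standardize log band power to the pooled rest-phase baseline.

    Per channel, the mean and sample SD (n-1 denominator) of the log power
    over all epochs inside the block rest phases define the z transform
    applied to every epoch.
    """
    rest_idx = rest_epoch_indices(timeline, power.n_epochs)
    if len(rest_idx) < 2:
        raise DataError("need >= 2 rest epochs to estimate the baseline")
    rest = power.log_power[:, rest_idx]
    mu = rest.mean(axis=1)
    sd = rest.std(axis=1, ddof=1)
    included = [i for i in range(power.log_power.shape[0])
                if i not in power.excluded]
    for i in included:
        if not sd[i] > 0:
            raise DataError(f"zero rest-baseline SD in channel "
                            f"'{power.channel_names[i]}'")
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (power.log_power - mu[:, None]) / sd_safe[:, None]
    return ZScoredHGA(z=z, baseline_mean=mu, baseline_sd=sd,
                      epoch_start_times=power.epoch_start_times,
                      channel_names=list(power.channel_names),
                      excluded=power.excluded, rest_epochs=rest_idx)


def extract_trial_samples(z: ZScoredHGA,
                          timeline: EventTimeline) -> TrialSampleMatrix:
    """Score every grasping trial by its 0.4-1.0 s window mean.

    Returns an electrodes x blocks x trials matrix plus the per-epoch z
    values inside each window.
    """
    cues = timeline.close_cues()
    if len(cues) == 0:
        raise DataError("timeline contains no close_cue events")
    n_blocks = int(cues["block"].max())
    n_trials = int(cues["trial"].max())
    n_ch = z.n_channels
    hga = np.full((n_ch, n_blocks, n_trials), np.nan)
    window_z = np.full((n_ch, n_blocks, n_trials, 6), np.nan)
    for _, row in cues.iterrows():
        b, t = int(row["block"]) - 1, int(row["trial"]) - 1
        win = evaluation_window(float(row["onset_s"]), z.n_epochs)
        vals = z.z[:, win.start:win.stop]
        window_z[:, b, t, :] = vals
        hga[:, b, t] = vals.mean(axis=1)
    if np.isnan(hga).any():
        raise DataError("missing cue events: trial sample matrix incomplete")
    return TrialSampleMatrix(hga=hga, window_z=window_z,
                             channel_names=list(z.channel_names),
                             excluded=z.excluded)


def preprocess(rec: ContinuousRecording,
               timeline: EventTimeline) -> ZScoredHGA:
    """Run the full signal chain on a continuous recording."""
    rec = remove_drift(rec)
    rec = common_average_reference(rec)
    rec = bandpass_hga(rec)
    env = envelope_downsample(rec)
    power = epoch_log_bandpower(env, rec.channel_names, rec.excluded)
    return zscore_to_rest(power, timeline)
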