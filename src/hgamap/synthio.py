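"""Paradigm-locked synthetic multichannel ECoG with planted ground truth.

Each channel is 1/f^alpha background noise (spectrally shaped white Gaussian
noise, optionally mixed with a shared component and mains sinusoid).  On
responsive channels every close cue adds a burst of 60-170 Hz band-limited
noise under a smooth unimodal envelope (onset ~0.3 s post-cue, peaking inside
the 100-ms scoring epoch labelled 0.7 s).  Burst amplitude for block b,
trial t is
``burst_gain * s(t) * l(b)``, where the short-term profile ``s`` and
long-term profile ``l`` plant within-block and across-block attenuation.
Ground-truth responsiveness and attenuation flags are derived from the
configuration alone, so recovery tests are well-posed.

Not simulated: volume conduction, cortical geometry, epileptiform artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .paradigm import ParadigmSpec, EventTimeline, build_timeline
from .sigproc import ContinuousRecording

#: Default per-trial (short-term) amplitude multipliers s(1..10): maximal on
#: the first trial, declining to trial 5, rebounding over 6-8, dipping at 9-10.
DEFAULT_SHORT_TERM = (1.00, 0.80, 0.70, 0.66, 0.62, 0.66, 0.70, 0.72, 0.55, 0.52)

#: Default per-block (long-term) amplitude multipliers l(1..10): a drop after
#: the first block followed by a near-plateau.
DEFAULT_LONG_TERM = (1.00, 0.70, 0.68, 0.66, 0.65, 0.64, 0.63, 0.62, 0.62, 0.62)

#: Burst-amplitude scale (relative to unit-variance background) calibrated so
#: the full pipeline's grand-average first-trial z-curve peaks near 1.25.
DEFAULT_BURST_GAIN = 0.21

#: Physical scale of the written signal, microvolts per unit noise SD.
SIGNAL_SCALE_UV = 50.0

#: Default deepest hand-knob point per hemisphere, MNI152 RAS millimetres.
DEFAULT_SIGMA = {"left": (-37.0, -25.0, 58.0), "right": (37.0, -25.0, 58.0)}


def default_profiles(attenuation: bool = True):
    """Return the default (short-term, long-term) amplitude profiles.

    With ``attenuation=False`` both profiles are all ones (no planted
    attenuation).
    """
    if not attenuation:
        return np.ones(10), np.ones(10)
    return np.array(DEFAULT_SHORT_TERM), np.array(DEFAULT_LONG_TERM)


def default_electrode_layout(n_channels: int,
                             hemisphere: str = "left") -> pd.DataFrame:
    """Synthetic electrode table: a pseudo-grid over the sensorimotor cortex.

    Channels cycle through PreCG, PostCG, PreCG, other region labels;
    coordinates form a grid around the hand-knob area of the requested
    hemisphere.  This is a synthetic stand-in layout, not patient anatomy.
    """
    sign = -1.0 if hemisphere == "left" else 1.0
    regions = ["PreCG", "PostCG", "PreCG", "other"]
    rows = []
    for i in range(n_channels):
        rows.append({
            "name": f"E{i + 1:02d}",
            "x": sign * (34.0 + 4.0 * (i % 3)),
            "y": -40.0 + 8.0 * ((i // 3) % 5),
            "z": 72.0 - 6.0 * (i // 15),
            "region": regions[i % 4],
            "ground": False,
        })
    return pd.DataFrame(rows)


@dataclass
class SyntheticConfig:
    """Generator parameters standing in for unobserved physiology."""

    n_channels: int = 16
    fs: float = 1200.0
    #: defaults to the first half of the channels
    responsive_channels: Optional[Sequence[int]] = None
    burst_gain: float = DEFAULT_BURST_GAIN
    short_term_profile: Sequence[float] = DEFAULT_SHORT_TERM
    long_term_profile: Sequence[float] = DEFAULT_LONG_TERM
    noise_exponent: float = 1.0
    shared_noise_fraction: float = 0.3
    line_noise_hz: Optional[float] = None
    line_noise_amplitude: float = 0.1
    seed: int = 0
    electrode_layout: Optional[pd.DataFrame] = None
    block_gain_profile: Optional[Sequence[float]] = None
    attenuation_margin: float = 0.2
    # the envelope peaks mid-way through the 100-ms epoch whose start is
    # labelled 0.7 s, so the scored dynamics curve peaks at the 0.7-s step
    burst_peak_s: float = 0.75
    burst_rise_s: float = 0.15
    burst_fall_s: float = 0.25
    burst_span_s: float = 1.4

    def __post_init__(self):
        if self.n_channels < 2:
            raise ConfigError("need at least 2 channels")
        if self.fs < 1200 or abs(self.fs / 400 - round(self.fs / 400)) > 1e-9:
            raise ConfigError("fs must be >= 1200 Hz and divisible by 400")
        if self.responsive_channels is None:
            self.responsive_channels = tuple(range(self.n_channels // 2))
        self.responsive_channels = tuple(int(i) for i in self.responsive_channels)
        bad = [i for i in self.responsive_channels
               if not 0 <= i < self.n_channels]
        if bad:
            raise ConfigError(f"responsive channel indices out of range: {bad}")
        self.short_term_profile = np.asarray(self.short_term_profile, float)
        self.long_term_profile = np.asarray(self.long_term_profile, float)
        for name in ("short_term_profile", "long_term_profile"):
            if not np.all(getattr(self, name) > 0):
                raise ConfigError(f"{name} multipliers must be > 0")
        if not 0.0 <= self.shared_noise_fraction <= 1.0:
            raise ConfigError("shared_noise_fraction must be in [0, 1]")
        if self.electrode_layout is None:
            self.electrode_layout = default_electrode_layout(self.n_channels)
        if len(self.electrode_layout) != self.n_channels:
            raise ConfigError("electrode_layout rows must match n_channels")


@dataclass
class GroundTruth:
    """Planted per-channel labels, derivable from the config deterministically.

    A channel is short-term attenuated when the mean short-term multiplier
    over trials 7-9 falls below the mean over trials 1-3 by at least the
    configured relative margin (long-term analogously over blocks).
    """

    responsive: np.ndarray
    short_term_attenuated: np.ndarray
    long_term_attenuated: np.ndarray
    short_term_profile: np.ndarray
    long_term_profile: np.ndarray
    margin: float

    @staticmethod
    def _relative_drop(profile: np.ndarray) -> float:
        """Drop of the third group (positions 7-9, or the last third for
        shorter profiles) relative to the first group."""
        if len(profile) >= 9:
            early, late = profile[0:3], profile[6:9]
        else:
            k = max(1, len(profile) // 3)
            early, late = profile[:k], profile[-k:]
        return 1.0 - float(np.mean(late)) / float(np.mean(early))

    @classmethod
    def from_config(cls, config: SyntheticConfig) -> "GroundTruth":
        s, l = config.short_term_profile, config.long_term_profile
        st_drop = cls._relative_drop(s)
        lt_drop = cls._relative_drop(l)
        responsive = np.zeros(config.n_channels, dtype=bool)
        responsive[list(config.responsive_channels)] = True
        m = config.attenuation_margin
        return cls(
            responsive=responsive,
            short_term_attenuated=responsive & (st_drop >= m),
            long_term_attenuated=responsive & (lt_drop >= m),
            short_term_profile=np.asarray(s, float),
            long_term_profile=np.asarray(l, float),
            margin=m,
        )

    def to_json(self, path) -> None:
        doc = {
            "responsive": self.responsive.astype(int).tolist(),
            "short_term_attenuated": self.short_term_attenuated.astype(int).tolist(),
            "long_term_attenuated": self.long_term_attenuated.astype(int).tolist(),
            "short_term_profile": self.short_term_profile.tolist(),
            "long_term_profile": self.long_term_profile.tolist(),
            "margin": self.margin,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            responsive=np.asarray(doc["responsive"], bool),
            short_term_attenuated=np.asarray(doc["short_term_attenuated"], bool),
            long_term_attenuated=np.asarray(doc["long_term_attenuated"], bool),
            short_term_profile=np.asarray(doc["short_term_profile"], float),
            long_term_profile=np.asarray(doc["long_term_profile"], float),
            margin=float(doc["margin"]),
        )


def _streams(config: SyntheticConfig):
    """Deterministic per-role random generators spawned from the seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_channels + 1)
    noise = [np.random.default_rng(c) for c in children[: config.n_channels]]
    shared = np.random.default_rng(children[config.n_channels])
    burst = [np.random.default_rng(c)
             for c in children[config.n_channels + 1:]]
    return noise, shared, burst


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  alpha: float = 0.0, band: Optional[tuple] = None) -> np.ndarray:
    """Spectrally shaped white Gaussian noise, unit variance (unit RMS if band).

    ``alpha`` applies a 1/f^alpha power slope; ``band`` instead hard-masks the
    spectrum to [lo, hi] Hz (used for burst carriers).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if band is not None:
        lo, hi = band
        spec = np.where((freqs >= lo) & (freqs <= hi), spec, 0.0)
    elif alpha != 0.0:
        with np.errstate(divide="ignore"):
            scale = np.where(freqs > 0, freqs, np.inf) ** (-alpha / 2.0)
        spec = spec * scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    if rms == 0:
        raise ConfigError("degenerate noise spectrum: zero power")
    return x / rms


def generate_background(config: SyntheticConfig,
                        duration_s: float) -> np.ndarray:
    """Continuous multichannel 1/f^alpha background, channels x samples.

    Each channel mixes independent and shared unit-variance components with
    amplitude weights (1 - f_sh) and f_sh; an optional mains sinusoid is added
    afterwards.  Byte-identical output under a fixed (config, seed).
    """
    if not duration_s > 0:
        raise ConfigError(f"duration must be > 0, got {duration_s}")
    n = int(round(duration_s * config.fs))
    noise_rngs, shared_rng, _ = _streams(config)
    f_sh = config.shared_noise_fraction
    shared = (_shaped_noise(shared_rng, n, config.fs, config.noise_exponent)
              if f_sh > 0 else np.zeros(n))
    data = np.empty((config.n_channels, n))
    for i, rng in enumerate(noise_rngs):
        indep = _shaped_noise(rng, n, config.fs, config.noise_exponent)
        data[i] = (1.0 - f_sh) * indep + f_sh * shared
    if config.line_noise_hz is not None:
        t = np.arange(n) / config.fs
        data += config.line_noise_amplitude * np.sin(
            2 * np.pi * config.line_noise_hz * t)
    return data


def burst_envelope(t_rel: np.ndarray, peak_s: float = 0.75,
                   rise_s: float = 0.15, fall_s: float = 0.25) -> np.ndarray:
    """Asymmetric Gaussian bump peaking at ``peak_s`` after the cue.

    The rise side reaches ~3% of peak amplitude about 2.6 rise widths before
    the peak (~0.3 s post-cue at defaults); the slower fall mimics the
    lingering movement response.  Peak amplitude is 1.
    """
    t_rel = np.asarray(t_rel, float)
    width = np.where(t_rel < peak_s, rise_s, fall_s)
    return np.exp(-0.5 * ((t_rel - peak_s) / width) ** 2)


def _burst_gain_series(config: SyntheticConfig, timeline: EventTimeline,
                       n: int) -> np.ndarray:
    """Envelope-amplitude time series summing the per-trial bursts."""
    gain = np.zeros(n)
    s, l = config.short_term_profile, config.long_term_profile
    span = int(round(config.burst_span_s * config.fs))
    for _, row in timeline.close_cues().iterrows():
        b, t = int(row["block"]) - 1, int(row["trial"]) - 1
        if t >= len(s) or b >= len(l):
            raise ConfigError("attenuation profiles shorter than the paradigm")
        i0 = int(round(row["onset_s"] * config.fs))
        i1 = min(i0 + span, n)
        t_rel = np.arange(i1 - i0) / config.fs
        env = burst_envelope(t_rel, config.burst_peak_s,
                             config.burst_rise_s, config.burst_fall_s)
        gain[i0:i1] += config.burst_gain * s[t] * l[b] * env
    return gain


def _block_gain_series(config: SyntheticConfig, timeline: EventTimeline,
                       n: int) -> np.ndarray:
    """Per-block multiplicative background gain (baseline drift), or ones."""
    gain = np.ones(n)
    if config.block_gain_profile is None:
        return gain
    prof = np.asarray(config.block_gain_profile, float)
    rests = timeline.rest_phases()
    spec = timeline.spec
    for _, row in rests.iterrows():
        b = int(row["block"]) - 1
        if b >= len(prof):
            raise ConfigError("block_gain_profile shorter than n_blocks")
        i0 = int(round(row["onset_s"] * config.fs))
        i1 = min(i0 + int(round(spec.block_s * config.fs)), n)
        gain[i0:i1] = prof[b]
    return gain


def generate_recording(config: SyntheticConfig, spec: ParadigmSpec):
    """Simulate one session: (ContinuousRecording, EventTimeline, GroundTruth).

    Responsive channels receive, after every close cue, 60-170 Hz band-limited
    noise shaped by the burst envelope with amplitude
    ``burst_gain * s(trial) * l(block)``; other channels carry background
    only.  The written signal is scaled to a realistic microvolt range.
    """
    timeline = build_timeline(spec)
    if len(config.short_term_profile) != spec.trials_per_block:
        raise ConfigError("short_term_profile length must equal trials_per_block")
    if len(config.long_term_profile) != spec.n_blocks:
        raise ConfigError("long_term_profile length must equal n_blocks")
    n = int(round(timeline.session_s * config.fs))
    data = generate_background(config, timeline.session_s)
    data *= _block_gain_series(config, timeline, n)
    gain = _burst_gain_series(config, timeline, n)
    _, _, burst_rngs = _streams(config)
    from .sigproc import HGA_BAND
    for ch in config.responsive_channels:
        carrier = _shaped_noise(burst_rngs[ch], n, config.fs, band=HGA_BAND)
        data[ch] += carrier * gain
    data *= SIGNAL_SCALE_UV
    layout = config.electrode_layout
    excluded = frozenset(np.flatnonzero(layout["ground"].to_numpy(bool)))
    rec = ContinuousRecording(data=data, fs=config.fs,
                              channel_names=list(layout["name"]),
                              excluded=excluded)
    return rec, timeline, GroundTruth.from_config(config)
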