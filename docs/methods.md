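# Methods

## Paradigm model

A session is `pre_rest_s` of initial rest followed by `n_blocks` blocks, each
a `rest_s` baseline phase and `trials_per_block` grasping trials of
`close_s + open_s` seconds. Defaults (10 s, 10 blocks, 12 s, 10 trials,
0.6 s + 0.6 s) give a 250-s session with 100 trials. All phase durations must
be multiples of the 100-ms analysis epoch, so every cue onset falls exactly
on the epoch grid; the time origin is the recording start, epochs are 0-based
half-open 100-ms intervals, and the timeline is built with integer epoch
arithmetic so that the phases tile the session without float drift.

A trial is one close+open pair referenced to its close cue; its HGA score is
the mean z over the six epochs covering 0.4–1.0 s after the cue. Trials
1–3/4–6/7–9 of each block form the short-term (nonresting) groups NR1–3 and
blocks 1–3/4–6/7–9 form the long-term (resting) groups R1–3; the 10th trial
of each block and the 10th block are excluded to balance the subgroups. With
the defaults each NR group holds 3 positions × 10 blocks = 30 samples per
electrode and each R group 3 blocks × 9 trials = 27. (A ×3 convention that
would count three samples per trial — giving 90/81 — is also emitted in the
report metadata for comparability; all statistics here use one sample per
trial.)

## Signal chain

Stage order is fixed: drift removal → common average reference → band-pass →
Hilbert envelope → downsample → 100-ms log band-power → rest z-scoring.

- **Filtering** is zero-phase (`sosfiltfilt`), so each 4th-order Butterworth
  pass acts twice on the magnitude while group delay cancels — this
  preserves the 300/700-ms response latency landmarks, which matter more
  here than causal filtering. The drift filter is a 2-Hz high-pass; the
  high-gamma band-pass is a cascade of a 60-Hz high-pass and a 170-Hz
  low-pass, each order 4.
- **Common average reference** subtracts the instantaneous mean of the
  included channels from each included channel; ground/bad channels pass
  through untouched and never enter the average or any later statistic.
- **Envelope** is the magnitude of the analytic signal at the native rate,
  reduced to 400 Hz by averaging non-overlapping groups of `fs/400` samples
  (a crude but adequate anti-alias step for a nonnegative envelope; the
  sampling rate must be ≥ 1200 Hz and divisible by 400).
- **Band power** is the mean squared envelope per 100-ms epoch (40 samples at
  400 Hz), natural-log transformed; a trailing partial epoch is dropped and a
  zero-power epoch is a hard error naming channel and epoch.
- **z-scoring** uses the mean and sample SD (n−1) of the log power over all
  epochs fully inside the ten numbered rest phases, pooled; the 10-s pre-rest
  is excluded because the baseline is defined by the block rest phases. No
  guard band is trimmed from the rests. By construction the pooled rest
  z-scores have mean 0 and sample SD 1 per channel (asserted to 1e-9).

Scaling the raw signal by k shifts every log-power epoch by 2·ln k and leaves
z-scores unchanged; this linearity is property-tested. Multi-run sessions
are processed per run (each z-scored against its own rests) and concatenated
at the trial-sample level.

## Electrode mapping

"Rest trials" are realized as contiguous 1.2-s pseudo-trials tiling each
rest phase (a trailing remainder is dropped), scored with the identical
0.4–1.0 s window rule — the symmetric counterpart of movement trials. Per
electrode a two-sided pooled-variance Student *t* (df = n₁+n₂−2) compares
movement and rest window means; p-values are Bonferroni-multiplied by the
number of recorded non-excluded electrodes in the case (configurable to
ROI-only counting), and significance additionally requires a PreCG or PostCG
region label. Two constant, equal conditions yield t = 0, p = 1; constant
unequal conditions are an error.

## Attenuation statistics

The Kruskal–Wallis omnibus uses mid-ranks with the standard tie-correction
divisor and a chi-square reference (k−1 df) at all sample sizes — cohort
pools here are large, so small-sample exact KW is out of scope. All-tied
data yield H = 0, p = 1. Dunn's pairwise z follows the rank-variance formula
with the tie term `Σ(t³−t)/(12(N−1))`, two-sided normal p, and Bonferroni
adjustment over the declared family: the 9 consecutive pairs for the
10-position cohort tests, and the 3 pairwise comparisons within NR (or R)
groups for per-electrode classification.

An electrode is **attenuated** when the (1,3) pair's adjusted p falls below
alpha *and* group 3 has the lower mean rank. The direction check plus
two-sided p mirrors common Dunn's-test software rather than a one-sided
test. Degenerate (all-equal) electrodes are classified not-attenuated and
flagged. Because the classification is rank-based it is invariant under any
strictly increasing transform of the samples, which is property-tested.

Cohort curves pool one sample per (significant electrode × block) trial with
no patient weighting, so 60 significant electrodes give 600 samples per
trial position and per block. Dynamics curves report mean ± 2·SEM (sample
SD/√n) per 100-ms step from −0.2 to +1.2 s around the cue for trial 1 vs 9,
merged NR1 vs NR3, and block 1 vs 10. The baseline-drift test pools rest
epochs of blocks 1–3 against 7–9 with the shared Mann–Whitney
implementation.

The Mann–Whitney p is exact (scipy's enumeration) when n₁+n₂ ≤ 12 with no
ties, otherwise a normal approximation with tie correction and a continuity
correction shrunk toward the null (so identical samples give p = 1). Fisher's
exact test is two-sided in the "sum of no-more-probable tables" sense. Both
are cross-checked in the test suite against independent brute-force
enumeration oracles, as are Kruskal–Wallis and Dunn against direct-formula
oracles (1e-10 on fixtures with ties).

## Spatial analysis

The hand-knob reference ("sigma") is a per-hemisphere configuration input in
MNI152 RAS millimetres, defaulting to (±37, −25, 58); anatomy pipelines are
out of scope and the point is normally read off the individual template.
Electrode hemisphere follows the sign of x; a midline electrode is assigned
the configured default hemisphere with a warning. The 2×2 contingency is
region (PreCG/PostCG) × attenuated among significant electrodes — one
possible reading of a gyrus-by-attenuation association test, recorded as an
interpretation in the report metadata.

## Synthetic generator

The generator emulates the study conditions, not the full physics of ECoG:

- **Background**: white Gaussian noise spectrally shaped to 1/f^α (α = 1 by
  default), unit variance per channel, mixed as `(1−f_sh)·independent +
  f_sh·shared` with `f_sh = 0.3`, plus an optional mains sinusoid. Every
  random stream is spawned deterministically from the seed, so output is
  byte-identical for identical configuration.
- **Movement response**: on responsive channels each close cue adds
  band-limited (hard spectral mask, 60–170 Hz) unit-RMS noise under an
  asymmetric Gaussian envelope (rise SD 0.15 s, fall SD 0.25 s). The
  envelope peaks at 0.75 s — the midpoint of the 100-ms epoch labelled
  0.7 s — so the scored dynamics curve peaks at the 0.7-s step; the rise
  reaches ~3% of peak around 0.3 s post-cue. Amplitude for block b, trial t
  is `burst_gain · s(t) · l(b)`.
- **Default profiles**: s = (1.00, 0.80, 0.70, 0.66, 0.62, 0.66, 0.70, 0.72,
  0.55, 0.52) — strongest first trial, decay to trial 5, rebound over trials
  6–8, late dip; l = (1.00, 0.70, 0.68, 0.66, 0.65, 0.64, 0.63, 0.62, 0.62,
  0.62) — a drop after block 1 then a near-plateau. `burst_gain = 0.21` was
  calibrated once so the full pipeline's grand-average first-trial z-curve
  over ≥ 20 responsive channels peaks near 1.25 z at the 0.7-s step; the
  ninth-trial peak then lands near 0.45 z.
- **Ground truth**: a channel is flagged short-term attenuated when the mean
  of s over trials 7–9 drops ≥ 20% (configurable margin) below the mean over
  trials 1–3; long-term analogously over blocks. The margin makes recovery
  tests well-posed where the study defines attenuation only via
  significance. An optional per-block background gain profile plants
  baseline drift for testing the drift comparison.

Not simulated: volume conduction, cortical geometry, epileptiform or
movement artifacts, electrode impedance effects. Passing recovery tests
therefore demonstrates the correctness of the analysis chain under the
planted model — not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance cohorts use 8–64 channels at 1200 Hz over the 250-s
default session, 20 seeded replicates for planted-effect recovery and 200
sample-level replicates for false-positive calibration — sizes chosen to
make the statistical assertions stable at desk scale. The classifier's null
false-positive simulations draw trial samples directly (iid normal, SD 0.45,
matching the empirical window-mean spread) because the classifier consumes
only the trial-sample matrix. Tolerances: filter magnitudes are compared to
the analog two-pass Butterworth cascade within 1–2% (the bilinear design
deviates from the analog prototype by < 1% at the tested frequencies); rank
statistics to 1e-10 against oracles; rest standardization to 1e-9.

## Known limitations

- Per-electrode attenuation classification at the default (paper-scale)
  contrast is conservative: with 30/27 samples per group and Bonferroni over
  three pairs, only strong attenuation is flagged — consistent with the
  modest attenuated fractions the method reports on real cohorts.
- The chi-square omnibus and normal Dunn reference are asymptotic; per-
  electrode group sizes (30/27) are adequate but not large.
- EDF files are read (via MNE) but not written; the canonical serialization
  is the delimited matrix + JSON sidecar.
- The spatial stage tests association with a single reference point per
  hemisphere; it does not model distance along the cortical surface.
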