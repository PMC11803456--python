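"""Electrode significance mapping: movement HGA versus rest pseudo-trials.

Each 12-s rest phase is partitioned into contiguous 1.2-s pseudo-trials that
are scored with the identical 0.4-1.0 s window rule as movement trials.  Per
electrode, a two-sample two-sided Student t test (pooled variance) compares
the movement and rest window means; p-values are Bonferroni-corrected by the
number of recorded, non-excluded electrodes in the case, and significance
additionally requires membership of the sensorimotor region of interest
(PreCG or PostCG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .paradigm import (EPOCH_S, TRIAL_S_DEFAULT, EventTimeline,
                       evaluation_window)
from .sigproc import TrialSampleMatrix, ZScoredHGA

ALPHA = 0.05


def rest_pseudotrials(timeline: EventTimeline,
                      pseudo_s: float = TRIAL_S_DEFAULT) -> pd.DataFrame:
    """Partition every rest phase into contiguous 1.2-s pseudo-trial onsets.

    A trailing remainder shorter than one pseudo-trial is dropped.  Returns a
    frame with columns block, k (1-based position within the rest) and
    onset_s; the default paradigm yields 10 rests x 10 = 100 pseudo-trials.
    """
    rows = []
    for _, row in timeline.rest_phases().iterrows():
        n = int(np.floor(row["duration_s"] / pseudo_s + 1e-9))
        if n == 0:
            raise DataError(f"rest phase of {row['duration_s']} s is shorter "
                            f"than one {pseudo_s}-s pseudo-trial")
        for k in range(n):
            rows.append({"block": int(row["block"]), "k": k + 1,
                         "onset_s": float(row["onset_s"]) + k * pseudo_s})
    return pd.DataFrame(rows)


def score_windows(z: ZScoredHGA, onsets: Sequence[float]) -> np.ndarray:
    """Window-mean z per (channel, onset) using the 0.4-1.0 s rule."""
    out = np.empty((z.n_channels, len(onsets)))
    for j, onset in enumerate(onsets):
        win = evaluation_window(float(onset), z.n_epochs)
        out[:, j] = z.z[:, win.start:win.stop].mean(axis=1)
    return out


@dataclass
class SignificanceResult:
    """Per-electrode t statistics and Bonferroni-corrected significance."""

    table: pd.DataFrame
    correction_n: int

    @property
    def significant_indices(self) -> np.ndarray:
        return self.table.loc[self.table["significant"],
                              "channel_index"].to_numpy(int)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def electrode_significance(move: np.ndarray, rest: np.ndarray,
                           correction_n: int,
                           in_roi: Sequence[bool],
                           channel_names: Optional[Sequence[str]] = None,
                           regions: Optional[Sequence[str]] = None,
                           alpha: float = ALPHA) -> SignificanceResult:
    """Student t (pooled variance, two-sided) per electrode, Bonferroni by
    ``correction_n``; significant = in-ROI and corrected p < alpha.

    ``move`` and ``rest`` are electrodes x samples matrices of window-mean z.
    """
    move = np.asarray(move, float)
    rest = np.asarray(rest, float)
    if move.ndim != 2 or rest.ndim != 2 or move.shape[0] != rest.shape[0]:
        raise DataError("move and rest must be electrodes x samples matrices")
    if move.shape[1] < 2 or rest.shape[1] < 2:
        raise DataError("need >= 2 samples per condition per electrode")
    if correction_n < 1:
        raise DataError("correction_n must be >= 1")
    in_roi = np.asarray(in_roi, bool)
    n_el = move.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_el)]
    t_vals = np.empty(n_el)
    p_vals = np.empty(n_el)
    for i in range(n_el):
        m, r = move[i], rest[i]
        if m.var(ddof=1) == 0 and r.var(ddof=1) == 0:
            if m.mean() == r.mean():
                t_vals[i], p_vals[i] = 0.0, 1.0
            else:
                raise DataError(f"zero variance in both conditions of "
                                f"electrode '{channel_names[i]}' with unequal "
                                "means: t undefined")
        else:
            t_vals[i], p_vals[i] = stats.ttest_ind(m, r, equal_var=True)
    p_bonf = np.minimum(1.0, p_vals * correction_n)
    table = pd.DataFrame({
        "channel": list(channel_names),
        "channel_index": np.arange(n_el),
        "region": list(regions) if regions is not None else [""] * n_el,
        "in_roi": in_roi,
        "t": t_vals,
        "p": p_vals,
        "p_bonferroni": p_bonf,
        "significant": in_roi & (p_bonf < alpha),
        "n_move": move.shape[1],
        "n_rest": rest.shape[1],
        "correction_n": int(correction_n),
    })
    return SignificanceResult(table=table, correction_n=int(correction_n))


def map_electrodes(trials: TrialSampleMatrix, z: ZScoredHGA,
                   timeline: EventTimeline,
                   in_roi: Sequence[bool],
                   regions: Optional[Sequence[str]] = None,
                   correction_scope: str = "all",
                   alpha: float = ALPHA) -> SignificanceResult:
    """End-to-end significance mapping from trial samples and rest windows.

    ``correction_scope`` selects the Bonferroni denominator: 'all' counts the
    recorded non-excluded electrodes (the default reading of correcting "for
    the number of electrodes in each case"), 'roi' counts ROI electrodes only.
    Excluded (ground/bad) channels are never significant.
    """
    pseudo = rest_pseudotrials(timeline)
    rest = score_windows(z, pseudo["onset_s"].to_numpy())
    move = trials.hga.reshape(trials.hga.shape[0], -1)
    included = np.array([i not in trials.excluded
                         for i in range(move.shape[0])])
    in_roi = np.asarray(in_roi, bool) & included
    if correction_scope == "all":
        correction_n = int(included.sum())
    elif correction_scope == "roi":
        correction_n = int(in_roi.sum())
    else:
        raise DataError(f"unknown correction scope {correction_scope!r}")
    res = electrode_significance(move, rest, max(correction_n, 1), in_roi,
                                 channel_names=trials.channel_names,
                                 regions=regions, alpha=alpha)
    res.table.loc[~included, "significant"] = False
    return res
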