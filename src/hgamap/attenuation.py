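"""Short- and long-term HGA attenuation: rank tests and classification.

Attenuation is assessed with the Kruskal-Wallis omnibus test followed by
Dunn's multiple-comparison test (Bonferroni adjustment over the declared pair
family).  Per electrode, trials 1-3/4-6/7-9 pooled over blocks form the NR1-3
groups (30 samples each under the default paradigm) and blocks 1-3/4-6/7-9
pooled over trials 1-9 form the R1-3 groups (27 each); a channel is
attenuated when group 3 is significantly below group 1 (two-sided adjusted
p < alpha together with a lower mean rank, matching common Dunn's-test
software rather than a one-sided test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .paradigm import EPOCH_S, EventTimeline
from .sigproc import TrialSampleMatrix, ZScoredHGA, rest_epoch_indices
from .spatial import mann_whitney

ALPHA = 0.05


def kruskal_wallis(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-tied data (every value identical) gives H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, float) for g in groups]
    nonempty = [g for g in groups if g.size]
    if len(nonempty) < 2:
        raise DataError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(nonempty)
    if pooled.size < 3:
        raise DataError("Kruskal-Wallis needs a total of >= 3 samples")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*nonempty)
    return float(h), float(p)


@dataclass(frozen=True)
class DunnPair:
    """One Dunn pairwise comparison between 1-based groups i and j."""

    i: int
    j: int
    z: float
    p_raw: float
    p_adjusted: float
    mean_rank_i: float
    mean_rank_j: float


def dunn_posthoc(groups: Sequence[np.ndarray],
                 family: Optional[Sequence[Tuple[int, int]]] = None,
                 ) -> List[DunnPair]:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment.

    For pair (i, j): z = (Rbar_i - Rbar_j) / sqrt(V * (1/n_i + 1/n_j)) with
    V = N(N+1)/12 - sum(t^3 - t) / (12(N-1)) over tie-group sizes t, two-sided
    normal p, and p_adjusted = min(1, m * p) for the declared family size m.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if family is None:
        family = [(i, j) for i in range(1, k + 1) for j in range(i + 1, k + 1)]
    for (i, j) in family:
        if not (1 <= i <= k and 1 <= j <= k):
            raise DataError(f"pair ({i}, {j}) outside the {k} groups")
        if groups[i - 1].size == 0 or groups[j - 1].size == 0:
            raise DataError(f"empty group in requested pair ({i}, {j})")
    pooled = np.concatenate([g for g in groups if g.size])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, pos = [], 0
    for g in groups:
        mean_ranks.append(ranks[pos: pos + g.size].mean() if g.size else np.nan)
        pos += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    m = len(family)
    out = []
    for (i, j) in family:
        ni, nj = groups[i - 1].size, groups[j - 1].size
        se = np.sqrt(var * (1.0 / ni + 1.0 / nj))
        if se > 0:
            z = (mean_ranks[i - 1] - mean_ranks[j - 1]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
        else:  # all observations tied
            z, p_raw = 0.0, 1.0
        out.append(DunnPair(i=i, j=j, z=float(z), p_raw=float(p_raw),
                            p_adjusted=float(min(1.0, m * p_raw)),
                            mean_rank_i=float(mean_ranks[i - 1]),
                            mean_rank_j=float(mean_ranks[j - 1])))
    return out


@dataclass
class RankTestResult:
    """Omnibus H/p plus the Dunn pair family on the same data."""

    H: float
    p_omnibus: float
    pairs: List[DunnPair]
    group_n: List[int] = field(default_factory=list)


def consecutive_position_test(samples: Sequence[np.ndarray]) -> RankTestResult:
    """Kruskal-Wallis over ordered positions with Dunn tests on the
    consecutive pairs (1,2) ... (k-1,k).

    Used for the 10 trial positions (pooled over significant electrodes and
    blocks) and identically for the 10 blocks.
    """
    samples = [np.asarray(g, float) for g in samples]
    empty = [i + 1 for i, g in enumerate(samples) if g.size == 0]
    if empty:
        raise DataError(f"missing samples at positions {empty}")
    h, p = kruskal_wallis(samples)
    family = [(i, i + 1) for i in range(1, len(samples))]
    pairs = dunn_posthoc(samples, family)
    return RankTestResult(H=h, p_omnibus=p, pairs=pairs,
                          group_n=[g.size for g in samples])


def _grouped(values: np.ndarray, axis_groups: str) -> List[np.ndarray]:
    """Split one electrode's blocks x trials matrix into NR or R groups."""
    if axis_groups == "nr":  # trials 1-3 / 4-6 / 7-9 over all blocks
        return [values[:, 0:3].ravel(), values[:, 3:6].ravel(),
                values[:, 6:9].ravel()]
    # blocks 1-3 / 4-6 / 7-9 over trials 1-9 (10th trial excluded)
    return [values[0:3, 0:9].ravel(), values[3:6, 0:9].ravel(),
            values[6:9, 0:9].ravel()]


GROUP_FAMILY = [(1, 2), (1, 3), (2, 3)]


@dataclass
class AttenuationResult:
    """Per-electrode NR/R classification with group summaries and tests."""

    table: pd.DataFrame
    tests: Dict[str, Dict[str, RankTestResult]] = field(default_factory=dict)

    @property
    def n_short_term(self) -> int:
        return int((self.table["nr_class"] == "attenuated").sum())

    @property
    def n_long_term(self) -> int:
        return int((self.table["r_class"] == "attenuated").sum())


def _classify_one(groups: List[np.ndarray], alpha: float):
    """Classify one electrode/grouping; returns (class, result, degenerate)."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        res = RankTestResult(H=0.0, p_omnibus=1.0,
                             pairs=dunn_posthoc(groups, GROUP_FAMILY),
                             group_n=[g.size for g in groups])
        return "not", res, True
    h, p = kruskal_wallis(groups)
    pairs = dunn_posthoc(groups, GROUP_FAMILY)
    res = RankTestResult(H=h, p_omnibus=p, pairs=pairs,
                         group_n=[g.size for g in groups])
    p13 = next(pr for pr in pairs if (pr.i, pr.j) == (1, 3))
    attenuated = (p13.p_adjusted < alpha) and (p13.mean_rank_j < p13.mean_rank_i)
    return ("attenuated" if attenuated else "not"), res, False


def classify_attenuation(trials: TrialSampleMatrix,
                         channels: Optional[Sequence[int]] = None,
                         alpha: float = ALPHA) -> AttenuationResult:
    """Classify each electrode as short-/long-term attenuated or not.

    ``channels`` restricts the classification (typically to the significant
    electrodes).  Electrodes with all-equal samples are classified
    not-attenuated and flagged degenerate.
    """
    if trials.n_blocks < 9 or trials.trials_per_block < 9:
        raise DataError("classification requires the full 10x10 grouped design")
    if channels is None:
        channels = [i for i in range(trials.hga.shape[0])
                    if i not in trials.excluded]
    rows, tests = [], {}
    for ch in channels:
        values = trials.hga[ch]
        row = {"channel": trials.channel_names[ch], "channel_index": int(ch)}
        tests[trials.channel_names[ch]] = {}
        for key, prefix in (("nr", "nr"), ("r", "r")):
            groups = _grouped(values, key)
            cls, res, degenerate = _classify_one(groups, alpha)
            tests[trials.channel_names[ch]][key] = res
            p13 = next(pr for pr in res.pairs if (pr.i, pr.j) == (1, 3))
            row[f"{prefix}_class"] = cls
            row[f"{prefix}_degenerate"] = degenerate
            row[f"{prefix}_H"] = res.H
            row[f"{prefix}_p_omnibus"] = res.p_omnibus
            row[f"{prefix}_p13_adjusted"] = p13.p_adjusted
            for g, arr in enumerate(groups, start=1):
                row[f"{prefix}{g}_n"] = arr.size
                row[f"{prefix}{g}_median"] = float(np.median(arr))
                row[f"{prefix}{g}_mean"] = float(arr.mean())
                row[f"{prefix}{g}_sem"] = float(arr.std(ddof=1) / np.sqrt(arr.size))
        rows.append(row)
    return AttenuationResult(table=pd.DataFrame(rows), tests=tests)


@dataclass
class DynamicsCurve:
    """Mean +/- 2 SEM of pooled HGA z per 100-ms step around the cue."""

    offsets_s: np.ndarray
    mean: np.ndarray
    sem2: np.ndarray
    n: np.ndarray


#: Epoch offsets relative to the cue for dynamics curves: -0.2 s .. +1.2 s.
DYNAMICS_OFFSETS = np.arange(-2, 12)

#: Cue selections for the standard dynamics comparisons.
DYNAMICS_SELECTIONS = {
    "trial_1": dict(trials=[1]),
    "trial_9": dict(trials=[9]),
    "nr1": dict(trials=[1, 2, 3]),
    "nr3": dict(trials=[7, 8, 9]),
    "block_1": dict(blocks=[1]),
    "block_10": dict(blocks=[10]),
}


def temporal_dynamics(z: ZScoredHGA, timeline: EventTimeline,
                      channels: Sequence[int],
                      selections: Optional[Dict[str, dict]] = None,
                      ) -> Dict[str, DynamicsCurve]:
    """Event-locked mean and 2-SEM curves over pooled (electrode x cue) samples.

    Default selections contrast trial 1 vs 9, merged NR1 vs NR3, and block 1
    vs block 10; every matching (channel, cue) pair contributes one sample
    per 100-ms step from -0.2 s to +1.2 s relative to the close cue.
    """
    if selections is None:
        selections = DYNAMICS_SELECTIONS
    channels = np.asarray(list(channels), dtype=int)
    if channels.size == 0:
        raise DataError("no channels selected for dynamics curves")
    cues = timeline.close_cues()
    out = {}
    for name, sel in selections.items():
        mask = np.ones(len(cues), dtype=bool)
        if "trials" in sel:
            mask &= cues["trial"].isin(sel["trials"]).to_numpy()
        if "blocks" in sel:
            mask &= cues["block"].isin(sel["blocks"]).to_numpy()
        onsets = cues.loc[mask, "onset_s"].to_numpy(float)
        if onsets.size == 0:
            raise DataError(f"selection '{name}' matches no cues")
        e0 = np.round(onsets / EPOCH_S).astype(int)
        idx = e0[:, None] + DYNAMICS_OFFSETS[None, :]
        if idx.min() < 0 or idx.max() >= z.n_epochs:
            raise DataError(f"dynamics window for '{name}' leaves the recording")
        vals = z.z[np.ix_(channels, idx.ravel())].reshape(
            channels.size, len(onsets), DYNAMICS_OFFSETS.size)
        pooled = vals.reshape(-1, DYNAMICS_OFFSETS.size)
        n = pooled.shape[0]
        if n <= 1:
            raise DataError(f"selection '{name}' pools n <= 1 samples")
        mean = pooled.mean(axis=0)
        sem2 = 2.0 * pooled.std(axis=0, ddof=1) / np.sqrt(n)
        out[name] = DynamicsCurve(offsets_s=DYNAMICS_OFFSETS * EPOCH_S,
                                  mean=mean, sem2=sem2,
                                  n=np.full(DYNAMICS_OFFSETS.size, n))
    return out


@dataclass
class BaselineDriftResult:
    """Early- vs late-block rest HGA comparison (Mann-Whitney U)."""

    median_blocks_1_3: float
    median_blocks_7_9: float
    U: float
    p: float
    n_early: int
    n_late: int


def baseline_drift_test(z: ZScoredHGA, timeline: EventTimeline,
                        channels: Sequence[int]) -> BaselineDriftResult:
    """Compare pooled rest-epoch z of blocks 1-3 against blocks 7-9.

    Detects baseline drift across the session; the two-sided Mann-Whitney U
    is the shared implementation from the spatial module.
    """
    channels = np.asarray(list(channels), dtype=int)
    rests = timeline.rest_phases()
    pools = {"early": [], "late": []}
    for _, row in rests.iterrows():
        b = int(row["block"])
        key = "early" if 1 <= b <= 3 else ("late" if 7 <= b <= 9 else None)
        if key is None:
            continue
        start = int(round(row["onset_s"] / EPOCH_S))
        count = int(np.floor(row["duration_s"] / EPOCH_S + 1e-9))
        stop = min(start + count, z.n_epochs)
        pools[key].append(z.z[np.ix_(channels, np.arange(start, stop))].ravel())
    early = np.concatenate(pools["early"]) if pools["early"] else np.array([])
    late = np.concatenate(pools["late"]) if pools["late"] else np.array([])
    if early.size == 0 or late.size == 0:
        raise DataError("empty rest pool for the baseline drift test")
    u, p = mann_whitney(early, late)
    return BaselineDriftResult(median_blocks_1_3=float(np.median(early)),
                               median_blocks_7_9=float(np.median(late)),
                               U=float(u), p=float(p),
                               n_early=early.size, n_late=late.size)


def pooled_position_samples(trials: TrialSampleMatrix,
                            channels: Sequence[int],
                            axis: str) -> List[np.ndarray]:
    """Pool one sample per (electrode, block) trial into ordered positions.

    ``axis='trial'`` gives one pool per trial position (over electrodes x
    blocks); ``axis='block'`` one pool per block (over electrodes x trials).
    Every significant electrode contributes flatly, so 60 electrodes over 10
    blocks yield 600 samples per trial position and per block.
    """
    channels = np.asarray(list(channels), dtype=int)
    hga = trials.hga[channels]
    if axis == "trial":
        return [hga[:, :, t].ravel() for t in range(trials.trials_per_block)]
    if axis == "block":
        return [hga[:, b, :].ravel() for b in range(trials.n_blocks)]
    raise DataError(f"unknown pooling axis {axis!r}")
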