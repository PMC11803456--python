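"""Experimental timeline for the repetitive-grasping mapping paradigm.

The paradigm is a 10-s pre-task rest followed by ``n_blocks`` blocks, each a
rest phase (baseline) and a train of grasping trials.  Every trial is one
"close the hand" cue followed by one "open the hand" cue; high-gamma activity
is scored in a fixed window after the close cue.  Trials within a block are
grouped into nonresting groups NR1-3 (trials 1-3/4-6/7-9) and blocks into
resting groups R1-3 (blocks 1-3/4-6/7-9); the 10th trial of each block and the
10th block are excluded from grouping to balance the subgroups.

All phase durations are multiples of the 100-ms analysis epoch, so cue onsets
fall exactly on the epoch grid (time origin = recording start, 0-based epoch
indices, half-open intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: Analysis epoch length in seconds (100 ms band-power epochs).
EPOCH_S = 0.1

#: Duration of one grasping trial scored against its close cue.
TRIAL_S_DEFAULT = 1.2

EVENT_COLUMNS = ["onset_s", "duration_s", "label", "block", "trial"]
EVENT_LABELS = ("pre_rest", "rest", "close_cue", "open_cue")


def _epochs(duration_s: float, what: str) -> int:
    """Convert a duration to an integer number of 100-ms epochs or fail."""
    n = duration_s / EPOCH_S
    if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
        raise ConfigError(f"{what} = {duration_s} s is not a multiple of the "
                          f"{EPOCH_S}-s epoch grid")
    return int(round(n))


@dataclass(frozen=True)
class ParadigmSpec:
    """Parametric description of the block/trial structure.

    Defaults reproduce the 250-s session: 10-s pre-rest, then 10 blocks of
    12-s rest + 10 grasping trials of 0.6-s close + 0.6-s open cues.
    """

    pre_rest_s: float = 10.0
    n_blocks: int = 10
    rest_s: float = 12.0
    trials_per_block: int = 10
    close_s: float = 0.6
    open_s: float = 0.6

    def __post_init__(self):
        for name in ("pre_rest_s", "rest_s", "close_s", "open_s"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("n_blocks", "trials_per_block"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        # cue-grid alignment is guaranteed by construction when all phase
        # durations are multiples of the epoch
        for name in ("pre_rest_s", "rest_s", "close_s", "open_s"):
            _epochs(getattr(self, name), name)

    @property
    def trial_s(self) -> float:
        return self.close_s + self.open_s

    @property
    def grasp_s(self) -> float:
        """Duration of the grasping phase of one block."""
        return self.trials_per_block * self.trial_s

    @property
    def block_s(self) -> float:
        return self.rest_s + self.grasp_s

    @property
    def session_s(self) -> float:
        """Total session duration from recording start."""
        return self.pre_rest_s + self.n_blocks * self.block_s

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class EventTimeline:
    """Ordered event list tiling the session exactly.

    ``events`` has columns onset_s, duration_s, label, block, trial; block and
    trial are 1-based and <NA> for the pre-task rest (and trial is <NA> for
    rest phases).
    """

    events: pd.DataFrame
    session_s: float
    spec: Optional[ParadigmSpec] = field(default=None, repr=False)

    def __post_init__(self):
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise DataError(f"event table missing columns {missing}")
        if not ev["onset_s"].is_monotonic_increasing:
            raise DataError("event onsets must be non-decreasing")
        bad = set(ev["label"]) - set(EVENT_LABELS)
        if bad:
            raise DataError(f"unknown event labels {sorted(bad)}")

    def close_cues(self) -> pd.DataFrame:
        return self.events[self.events["label"] == "close_cue"].reset_index(drop=True)

    def rest_phases(self) -> pd.DataFrame:
        return self.events[self.events["label"] == "rest"].reset_index(drop=True)

    @property
    def n_blocks(self) -> int:
        return int(self.events["block"].max())

    @property
    def trials_per_block(self) -> int:
        return int(self.events["trial"].max())

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTimeline":
        path = Path(path)
        if not path.exists():
            raise DataError(f"event table not found: {path}")
        ev = pd.read_csv(path, sep="\t",
                         dtype={"onset_s": float, "duration_s": float,
                                "label": str, "block": "Int64", "trial": "Int64"})
        session_s = float((ev["onset_s"] + ev["duration_s"]).max())
        return cls(events=ev, session_s=session_s)


def build_timeline(spec: ParadigmSpec) -> EventTimeline:
    """Expand a :class:`ParadigmSpec` into the full event list.

    The session ends at ``pre_rest_s + n_blocks * (rest_s + trials_per_block *
    (close_s + open_s))`` seconds; phase durations tile it exactly.
    """
    rows = []
    # integer epoch bookkeeping avoids float drift over hundreds of events
    t = 0
    pre, rest = _epochs(spec.pre_rest_s, "pre_rest_s"), _epochs(spec.rest_s, "rest_s")
    close, open_ = _epochs(spec.close_s, "close_s"), _epochs(spec.open_s, "open_s")
    rows.append((0.0, spec.pre_rest_s, "pre_rest", pd.NA, pd.NA))
    t += pre
    for b in range(1, spec.n_blocks + 1):
        rows.append((t * EPOCH_S, spec.rest_s, "rest", b, pd.NA))
        t += rest
        for k in range(1, spec.trials_per_block + 1):
            rows.append((t * EPOCH_S, spec.close_s, "close_cue", b, k))
            t += close
            rows.append((t * EPOCH_S, spec.open_s, "open_cue", b, k))
            t += open_
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    ev["block"] = ev["block"].astype("Int64")
    ev["trial"] = ev["trial"].astype("Int64")
    session_s = t * EPOCH_S
    assert abs(session_s - spec.session_s) < 1e-9
    return EventTimeline(events=ev, session_s=session_s, spec=spec)


@dataclass(frozen=True)
class GroupAssignment:
    """NR/R group membership of one (block, trial) cell; ``None`` = excluded."""

    nr_group: Optional[int]
    r_group: Optional[int]


def assign_groups(block: int, trial: int) -> GroupAssignment:
    """Map a 1-based (block, trial) index pair to its NR and R groups.

    Trials 1-3/4-6/7-9 form NR1-3 and blocks 1-3/4-6/7-9 form R1-3; the 10th
    trial of any block and the 10th block are excluded.
    """
    for name, v in (("block", block), ("trial", trial)):
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 10):
            raise ConfigError(f"{name} index must be in 1..10, got {v!r}")
    nr = None if trial == 10 else (trial - 1) // 3 + 1
    r = None if block == 10 else (block - 1) // 3 + 1
    return GroupAssignment(nr_group=nr, r_group=r)


#: Evaluation window relative to the close cue, in epochs: [0.4 s, 1.0 s).
WINDOW_START_EPOCHS = 4
WINDOW_LEN_EPOCHS = 6


def evaluation_window(cue_onset_s: float, n_epochs: Optional[int] = None) -> range:
    """Half-open range of 0-based 100-ms epochs covering [onset+0.4, onset+1.0).

    ``n_epochs``, when given, bounds the recording; a window reaching past it
    is an error.  The cue onset must sit on the epoch grid.
    """
    g = cue_onset_s / EPOCH_S
    if abs(g - round(g)) > 1e-6:
        raise DataError(f"cue onset {cue_onset_s} s is not on the "
                        f"{EPOCH_S}-s epoch grid")
    start = int(round(g)) + WINDOW_START_EPOCHS
    stop = start + WINDOW_LEN_EPOCHS
    if start < 0 or (n_epochs is not None and stop > n_epochs):
        raise DataError(f"evaluation window [{start}, {stop}) epochs extends "
                        f"beyond the recording ({n_epochs} epochs)")
    return range(start, stop)
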