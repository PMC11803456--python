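"""Spatial statistics: gyrus contingency and hand-knob distances.

Relates attenuation status to cortical location in MNI152 space (RAS,
millimetres): a 2x2 Fisher exact test of region (PreCG/PostCG) against
attenuation among significant electrodes, and a Mann-Whitney comparison of
the Euclidean distances from each electrode to the deepest point of the
hand-knob fold ("sigma", supplied per hemisphere in the configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

ELECTRODE_COLUMNS = ["name", "x", "y", "z", "region", "ground"]
ROI_REGIONS = ("PreCG", "PostCG")


@dataclass
class ElectrodeTable:
    """Electrode names, MNI coordinates, region labels and ground flags."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in ELECTRODE_COLUMNS if c not in t.columns]
        if missing:
            raise DataError(f"electrode table missing columns {missing}")
        if t["name"].duplicated().any():
            dups = t.loc[t["name"].duplicated(), "name"].tolist()
            raise DataError(f"duplicate electrode names: {dups}")
        coords = t[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise DataError("electrode coordinates must be finite")
        bad = set(t["region"]) - {"PreCG", "PostCG", "other"}
        if bad:
            raise DataError(f"unknown region labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list:
        return list(self.table["name"])

    @property
    def in_roi(self) -> np.ndarray:
        return self.table["region"].isin(ROI_REGIONS).to_numpy()

    @property
    def ground(self) -> np.ndarray:
        return self.table["ground"].to_numpy(bool)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeTable":
        path = Path(path)
        if not path.exists():
            raise DataError(f"electrode table not found: {path}")
        t = pd.read_csv(path, sep="\t")
        if "ground" in t.columns:
            t["ground"] = t["ground"].astype(bool)
        return cls(table=t)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U with mid-ranks.

    Returns (U_x, p).  The p-value is exact (full enumeration) when
    n_x + n_y <= 12 and the pooled data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney requires non-empty samples on both sides")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(counts > 1)
    if n <= 12 and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)
        return u_x, p
    mu = nx * ny / 2.0
    tie_term = float(np.sum(counts ** 3 - counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied
        return u_x, 1.0
    d = abs(u_x - mu) - 0.5  # continuity correction toward the null
    z = max(d, 0.0) / np.sqrt(var)
    return u_x, float(min(1.0, 2.0 * stats.norm.sf(z)))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of tables
    (at fixed margins) no more probable than the observed one."""
    table = np.asarray(table)
    if table.shape != (2, 2) or table.sum() == 0:
        raise DataError("Fisher test needs a non-empty 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def gyrus_contingency(attenuated: Sequence[bool],
                      regions: Sequence[str]) -> Tuple[np.ndarray, float]:
    """2x2 counts (PreCG/PostCG x attenuated/not) and two-sided Fisher p.

    Applied to the significant electrodes only; every electrode must carry a
    PreCG or PostCG label.
    """
    attenuated = np.asarray(attenuated, bool)
    regions = np.asarray(regions, dtype=object)
    if attenuated.size == 0:
        raise DataError("empty contingency: no electrodes given")
    bad = sorted(set(regions) - set(ROI_REGIONS))
    if bad:
        raise DataError(f"contingency requires PreCG/PostCG labels, got {bad}")
    pre = regions == "PreCG"
    counts = np.array([
        [int((pre & attenuated).sum()), int((pre & ~attenuated).sum())],
        [int((~pre & attenuated).sum()), int((~pre & ~attenuated).sum())],
    ])
    return counts, fisher_exact_2x2(counts)


def handknob_distances(table: ElectrodeTable,
                       sigma: Dict[str, Sequence[float]],
                       default_hemisphere: str = "left") -> np.ndarray:
    """Euclidean distance (mm) from each electrode to its hemisphere's sigma.

    Hemisphere follows the sign of the MNI x coordinate (negative = left); an
    electrode exactly on the midline is assigned the configured default
    hemisphere with a warning.
    """
    for hemi in ("left", "right"):
        if hemi not in sigma or len(sigma[hemi]) != 3:
            raise DataError(f"sigma point for hemisphere '{hemi}' missing or "
                            "not 3-dimensional")
    if default_hemisphere not in ("left", "right"):
        raise DataError(f"unknown default hemisphere {default_hemisphere!r}")
    coords = table.table[["x", "y", "z"]].to_numpy(float)
    dists = np.empty(len(coords))
    for i, (x, y, z) in enumerate(coords):
        if x < 0:
            hemi = "left"
        elif x > 0:
            hemi = "right"
        else:
            hemi = default_hemisphere
            warnings.warn(f"electrode '{table.names[i]}' at x = 0 assigned to "
                          f"the {hemi} hemisphere", stacklevel=2)
        dists[i] = np.linalg.norm(np.array([x, y, z]) - np.asarray(sigma[hemi],
                                                                   float))
    return dists


@dataclass
class SpatialResult:
    """Contingency and distance comparison for one attenuation grouping."""

    contingency: np.ndarray
    fisher_p: float
    distances: np.ndarray
    U: float
    mwu_p: float
    median_attenuated: float
    median_nonattenuated: float
    n_attenuated: int
    n_nonattenuated: int


def spatial_analysis(table: ElectrodeTable,
                     attenuated: Sequence[bool],
                     sigma: Optional[Dict[str, Sequence[float]]] = None,
                     default_hemisphere: str = "left") -> SpatialResult:
    """Run the gyrus contingency and hand-knob distance tests together.

    ``table`` and ``attenuated`` cover the significant electrodes of one
    grouping (NR or R).  When one class is empty the Mann-Whitney comparison
    is undefined and reported as U = nan, p = 1.
    """
    if sigma is None:
        from .synthio import DEFAULT_SIGMA
        sigma = DEFAULT_SIGMA
    attenuated = np.asarray(attenuated, bool)
    if len(attenuated) != len(table):
        raise DataError("attenuation flags do not match the electrode table")
    counts, fisher_p = gyrus_contingency(attenuated,
                                         table.table["region"].to_numpy())
    dists = handknob_distances(table, sigma, default_hemisphere)
    att, non = dists[attenuated], dists[~attenuated]
    if att.size and non.size:
        u, p = mann_whitney(att, non)
    else:
        u, p = float("nan"), 1.0
    return SpatialResult(
        contingency=counts, fisher_p=fisher_p, distances=dists,
        U=u, mwu_p=p,
        median_attenuated=float(np.median(att)) if att.size else float("nan"),
        median_nonattenuated=float(np.median(non)) if non.size else float("nan"),
        n_attenuated=int(att.size), n_nonattenuated=int(non.size))
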