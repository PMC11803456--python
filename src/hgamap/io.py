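"""File formats: recordings, events, electrodes, result tables, reports.

Signals travel as a tab-separated samples x channels matrix with a JSON
sidecar naming the sampling rate and channels; European Data Format files are
read through MNE when given.  Every result table is tab-separated with a
header row; the run report is schema-versioned JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .sigproc import (ContinuousRecording, TrialSampleMatrix, ZScoredHGA,
                      DRIFT_CUTOFF_HZ, FILTER_ORDER, HGA_BAND, ENVELOPE_FS)
from .spatial import ElectrodeTable

REPORT_SCHEMA_VERSION = "1.0"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(rec: ContinuousRecording, path) -> Path:
    """Write a recording as TSV (samples x channels) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "excluded_channels": sorted(rec.channel_names[i] for i in rec.excluded),
        "n_samples": rec.n_samples,
        "units": "uV",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return path


def _read_recording_tsv(path: Path) -> ContinuousRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise DataError(f"delimited recording {path} requires the sidecar "
                        f"header {sidecar.name} (fs, channel names)")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("fs", "channel_names"):
        if key not in meta:
            raise DataError(f"sidecar {sidecar.name} missing '{key}'")
    df = pd.read_csv(path, sep="\t")
    names = meta["channel_names"]
    if list(df.columns) != list(names):
        raise DataError("sidecar channel names do not match the matrix header")
    if "n_samples" in meta and len(df) != meta["n_samples"]:
        raise DataError(f"sample-count mismatch: sidecar says "
                        f"{meta['n_samples']}, matrix has {len(df)}")
    excluded_names = set(meta.get("excluded_channels", []))
    excluded = frozenset(i for i, nm in enumerate(names)
                         if nm in excluded_names)
    return ContinuousRecording(data=df.to_numpy(float).T, fs=float(meta["fs"]),
                               channel_names=list(names), excluded=excluded)


def _read_recording_edf(path: Path) -> ContinuousRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return ContinuousRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                               channel_names=list(raw.ch_names))


def read_recording(path, fmt: str = "auto") -> ContinuousRecording:
    """Load a continuous recording from EDF or a delimited matrix + sidecar."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"recording not found: {path}")
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if fmt == "edf":
        return _read_recording_edf(path)
    if fmt == "tsv":
        return _read_recording_tsv(path)
    raise DataError(f"unknown recording format {fmt!r}")


def check_channels_match(rec: ContinuousRecording,
                         electrodes: ElectrodeTable) -> None:
    """Recording channels and electrode table must agree one-to-one."""
    rec_names, tab_names = list(rec.channel_names), electrodes.names
    if rec_names != tab_names:
        only_rec = sorted(set(rec_names) - set(tab_names))
        only_tab = sorted(set(tab_names) - set(rec_names))
        raise DataError(
            "channel mismatch between recording and electrode table; "
            f"only in recording: {only_rec}; only in table: {only_tab}; "
            f"order differs: {set(rec_names) == set(tab_names)}")


def filter_settings() -> dict:
    """The fixed signal-chain settings, recorded in sidecars and reports."""
    return {
        "drift_highpass_hz": DRIFT_CUTOFF_HZ,
        "hga_band_hz": list(HGA_BAND),
        "butterworth_order": FILTER_ORDER,
        "zero_phase": True,
        "envelope_fs": ENVELOPE_FS,
        "epoch_s": 0.1,
    }


def write_zscored(z: ZScoredHGA, path) -> Path:
    """Write z-scores as TSV (epoch rows x channel columns) plus sidecar."""
    path = Path(path)
    df = pd.DataFrame(z.z.T, columns=list(z.channel_names))
    df.insert(0, "epoch_start_s", z.epoch_start_times)
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "filter_settings": filter_settings(),
        "baseline_mean": dict(zip(z.channel_names,
                                  np.asarray(z.baseline_mean).tolist())),
        "baseline_sd": dict(zip(z.channel_names,
                                np.asarray(z.baseline_sd).tolist())),
        "excluded_channels": sorted(z.channel_names[i] for i in z.excluded),
        "epoch_indexing": "0-based, half-open 100-ms intervals from t=0",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return path


def read_zscored(path) -> ZScoredHGA:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    with open(_sidecar_path(path)) as fh:
        meta = json.load(fh)
    names = [c for c in df.columns if c != "epoch_start_s"]
    excluded_names = set(meta.get("excluded_channels", []))
    excluded = frozenset(i for i, nm in enumerate(names)
                         if nm in excluded_names)
    return ZScoredHGA(
        z=df[names].to_numpy(float).T,
        baseline_mean=np.array([meta["baseline_mean"][nm] for nm in names]),
        baseline_sd=np.array([meta["baseline_sd"][nm] for nm in names]),
        epoch_start_times=df["epoch_start_s"].to_numpy(float),
        channel_names=names, excluded=excluded)


def write_trial_samples(trials: TrialSampleMatrix, path) -> Path:
    """Long-format trial table: channel, block, trial, window mean and the
    six per-epoch z values (w0..w5, 0-based window epochs)."""
    path = Path(path)
    n_ch, n_b, n_t = trials.hga.shape
    ch_idx, b_idx, t_idx = np.meshgrid(np.arange(n_ch), np.arange(n_b),
                                       np.arange(n_t), indexing="ij")
    df = pd.DataFrame({
        "channel": np.asarray(trials.channel_names)[ch_idx.ravel()],
        "block": b_idx.ravel() + 1,
        "trial": t_idx.ravel() + 1,
        "hga": trials.hga.ravel(),
    })
    for w in range(trials.window_z.shape[-1]):
        df[f"w{w}"] = trials.window_z[..., w].ravel()
    df.to_csv(path, sep="\t", index=False)
    return path


def read_trial_samples(path, excluded: frozenset = frozenset()
                       ) -> TrialSampleMatrix:
    df = pd.read_csv(path, sep="\t")
    names = list(dict.fromkeys(df["channel"]))
    n_ch = len(names)
    n_b, n_t = int(df["block"].max()), int(df["trial"].max())
    w_cols = [c for c in df.columns if c.startswith("w")]
    hga = df["hga"].to_numpy(float).reshape(n_ch, n_b, n_t)
    window_z = (df[w_cols].to_numpy(float)
                .reshape(n_ch, n_b, n_t, len(w_cols)))
    return TrialSampleMatrix(hga=hga, window_z=window_z, channel_names=names,
                             excluded=excluded)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_report(report: dict, path) -> Path:
    path = Path(path)
    doc = dict(report)
    doc.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def validate_report(report: dict) -> None:
    """Minimal schema check for the run report."""
    required = ["schema_version", "seed", "stages", "summary"]
    missing = [k for k in required if k not in report]
    if missing:
        raise DataError(f"report missing required fields {missing}")
    if not isinstance(report["stages"], dict):
        raise DataError("report 'stages' must be an object")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_digest(doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()
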