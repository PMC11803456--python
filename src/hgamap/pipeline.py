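"""End-to-end pipeline: simulate/load -> preprocess -> map -> attenuate ->
spatial, with every artifact written to the output directory and a
schema-versioned JSON report tying the counts together."""

from __future__ import annotations

import logging
import time
import warnings as _warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as hio
from .attenuation import (baseline_drift_test, classify_attenuation,
                          consecutive_position_test, pooled_position_samples,
                          temporal_dynamics)
from .config import RunConfig
from .errors import HgaMapError, PipelineError
from .mapping import map_electrodes
from .paradigm import EventTimeline, build_timeline
from .sigproc import extract_trial_samples, preprocess
from .spatial import ElectrodeTable, spatial_analysis
from .synthio import GroundTruth, SyntheticConfig, generate_recording

logger = logging.getLogger("hgamap")

FILES = {
    "events": "events.tsv",
    "electrodes": "electrodes.tsv",
    "ground_truth": "ground_truth.json",
    "recording": "recording.tsv",
    "zscores": "hga_z.tsv",
    "trial_samples": "trial_samples.tsv",
    "significance": "significance.tsv",
    "attenuation": "attenuation.tsv",
    "dynamics": "dynamics.tsv",
    "consecutive": "consecutive_tests.tsv",
    "spatial": "spatial.tsv",
    "report": "report.json",
    "config": "config_used.yaml",
    "log": "run.log",
}


class Pipeline:
    """Stage-wise runner; stages can execute in memory or from files."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report: dict = {
            "schema_version": hio.REPORT_SCHEMA_VERSION,
            "seed": config.seed,
            "config": config.to_dict(include_output_dir=False),
            "stages": {},
            "summary": {},
            "metadata": {},
            "warnings": [],
        }
        # state filled by stages
        self.rec = None
        self.timeline: Optional[EventTimeline] = None
        self.electrodes: Optional[ElectrodeTable] = None
        self.ground_truth: Optional[GroundTruth] = None
        self.z = None
        self.trials = None
        self.significance = None
        self.attenuation = None

    def _path(self, key: str) -> Path:
        return self.out / FILES[key]

    def _stage(self, name: str):
        return _StageContext(self, name)

    # ------------------------------------------------------------------ acquire

    def acquire(self, write_recording: Optional[bool] = None):
        """Simulate a session or load recording/events/electrodes from disk."""
        with self._stage("acquire") as st:
            if self.cfg.simulate:
                overrides = dict(self.cfg.synthetic)
                overrides.setdefault("seed", self.cfg.seed)
                syn = SyntheticConfig(**overrides)
                self.rec, self.timeline, self.ground_truth = generate_recording(
                    syn, self.cfg.paradigm)
                self.electrodes = ElectrodeTable(syn.electrode_layout)
                self.timeline.to_tsv(self._path("events"))
                self.electrodes.to_tsv(self._path("electrodes"))
                self.ground_truth.to_json(self._path("ground_truth"))
                if write_recording or (write_recording is None
                                       and self.cfg.write_recording):
                    hio.write_recording(self.rec, self._path("recording"))
                st.info["mode"] = "simulate"
                doc = {k: v for k, v in overrides.items()
                       if k != "electrode_layout"}
                st.info["input_digests"] = {"synthetic_config":
                                            hio.config_digest(doc)}
            else:
                self.rec = hio.read_recording(self.cfg.recording,
                                              self.cfg.recording_format)
                self.timeline = EventTimeline.from_tsv(self.cfg.events)
                self.electrodes = ElectrodeTable.from_tsv(self.cfg.electrodes)
                hio.check_channels_match(self.rec, self.electrodes)
                ground = np.flatnonzero(self.electrodes.ground)
                self.rec.excluded = frozenset(
                    self.rec.excluded | set(int(i) for i in ground))
                st.info["mode"] = "load"
                st.info["input_digests"] = {
                    "recording": hio.file_digest(self.cfg.recording),
                    "events": hio.file_digest(self.cfg.events),
                    "electrodes": hio.file_digest(self.cfg.electrodes),
                }
            st.info["n_channels"] = self.rec.n_channels
            st.info["n_samples"] = self.rec.n_samples
            st.info["fs"] = self.rec.fs
            st.info["session_s"] = self.timeline.session_s

    def load_acquired(self):
        """Reload a previously simulated/copied session from the output dir."""
        self.rec = hio.read_recording(self._path("recording"))
        self.timeline = EventTimeline.from_tsv(self._path("events"))
        self.electrodes = ElectrodeTable.from_tsv(self._path("electrodes"))
        gt_path = self._path("ground_truth")
        if gt_path.exists():
            self.ground_truth = GroundTruth.from_json(gt_path)
        ground = np.flatnonzero(self.electrodes.ground)
        self.rec.excluded = frozenset(self.rec.excluded
                                      | set(int(i) for i in ground))

    # -------------------------------------------------------------- preprocess

    def run_preprocess(self):
        """Signal chain to z-scored HGA and the trial sample matrix."""
        with self._stage("preprocess") as st:
            self.z = preprocess(self.rec, self.timeline)
            self.trials = extract_trial_samples(self.z, self.timeline)
            hio.write_zscored(self.z, self._path("zscores"))
            hio.write_trial_samples(self.trials, self._path("trial_samples"))
            st.info["filter_settings"] = hio.filter_settings()
            st.info["n_epochs"] = self.z.n_epochs
            st.info["n_rest_epochs"] = int(len(self.z.rest_epochs))
            st.info["trial_matrix_shape"] = list(self.trials.hga.shape)

    def load_preprocessed(self):
        if self.timeline is None:
            self.timeline = EventTimeline.from_tsv(self._path("events"))
        if self.electrodes is None:
            self.electrodes = ElectrodeTable.from_tsv(self._path("electrodes"))
        self.z = hio.read_zscored(self._path("zscores"))
        self.trials = hio.read_trial_samples(self._path("trial_samples"),
                                             excluded=self.z.excluded)

    # --------------------------------------------------------------------- map

    def run_map(self):
        """Per-electrode movement-vs-rest significance inside the ROI."""
        with self._stage("map") as st:
            regions = self.electrodes.table["region"].to_numpy()
            self.significance = map_electrodes(
                self.trials, self.z, self.timeline,
                in_roi=self.electrodes.in_roi, regions=regions,
                correction_scope=self.cfg.correction_scope,
                alpha=self.cfg.alpha)
            hio.write_table(self.significance.table, self._path("significance"))
            st.info["correction_n"] = self.significance.correction_n
            st.info["correction_scope"] = self.cfg.correction_scope
            st.info["n_significant"] = self.significance.n_significant
            st.info["n_roi"] = int(self.electrodes.in_roi.sum())

    def load_significance(self):
        from .mapping import SignificanceResult
        table = hio.read_table(self._path("significance"))
        n = int(table["correction_n"].iloc[0]) if len(table) else 0
        self.significance = SignificanceResult(table=table, correction_n=n)

    # ---------------------------------------------------------------- attenuate

    def run_attenuate(self):
        """Classification, cohort position tests, dynamics, baseline drift."""
        with self._stage("attenuate") as st:
            sig_idx = self.significance.significant_indices
            st.info["n_significant"] = len(sig_idx)
            if len(sig_idx) == 0:
                self.report["summary"]["empty_significant_set"] = True
                hio.write_table(pd.DataFrame(
                    columns=["channel", "nr_class", "r_class"]),
                    self._path("attenuation"))
                hio.write_table(pd.DataFrame(
                    columns=["curve", "offset_s", "mean", "sem2", "n"]),
                    self._path("dynamics"))
                hio.write_table(pd.DataFrame(
                    columns=["axis", "i", "j", "z", "p_raw", "p_adjusted"]),
                    self._path("consecutive"))
                self._warn("no significant electrodes: attenuation tables "
                           "are empty")
                self.attenuation = None
                return
            self.attenuation = classify_attenuation(self.trials, sig_idx,
                                                    alpha=self.cfg.alpha)
            hio.write_table(self.attenuation.table, self._path("attenuation"))

            cons_rows = []
            for axis in ("trial", "block"):
                pools = pooled_position_samples(self.trials, sig_idx, axis)
                res = consecutive_position_test(pools)
                st.info[f"{axis}_omnibus"] = {"H": res.H, "p": res.p_omnibus,
                                              "n_per_position": res.group_n}
                for pr in res.pairs:
                    cons_rows.append({"axis": axis, "i": pr.i, "j": pr.j,
                                      "z": pr.z, "p_raw": pr.p_raw,
                                      "p_adjusted": pr.p_adjusted})
            hio.write_table(pd.DataFrame(cons_rows), self._path("consecutive"))

            curves = temporal_dynamics(self.z, self.timeline, sig_idx)
            dyn_rows = []
            for name, c in curves.items():
                for k in range(len(c.offsets_s)):
                    dyn_rows.append({"curve": name,
                                     "offset_s": c.offsets_s[k],
                                     "mean": c.mean[k], "sem2": c.sem2[k],
                                     "n": int(c.n[k])})
            hio.write_table(pd.DataFrame(dyn_rows), self._path("dynamics"))

            drift = baseline_drift_test(self.z, self.timeline, sig_idx)
            st.info["baseline_drift"] = {
                "median_blocks_1_3": drift.median_blocks_1_3,
                "median_blocks_7_9": drift.median_blocks_7_9,
                "U": drift.U, "p": drift.p,
            }

    # ------------------------------------------------------------------ spatial

    def run_spatial(self):
        """Gyrus contingency and hand-knob distances for NR and R groupings."""
        with self._stage("spatial") as st:
            if self.attenuation is None:
                self._warn("spatial stage needs attenuation results; skipped")
                self.report["stages"]["spatial"]["status"] = "skipped"
                return
            sig_idx = self.significance.significant_indices
            sub = ElectrodeTable(self.electrodes.table.iloc[sig_idx]
                                 .reset_index(drop=True))
            at = self.attenuation.table
            rows = {"channel": at["channel"], "region": sub.table["region"]}
            for key, col in (("nr", "nr_class"), ("r", "r_class")):
                flags = (at[col] == "attenuated").to_numpy()
                with _warnings.catch_warnings(record=True) as caught:
                    _warnings.simplefilter("always")
                    res = spatial_analysis(sub, flags, self.cfg.sigma,
                                           self.cfg.default_hemisphere)
                for w in caught:
                    self._warn(str(w.message))
                st.info[f"{key}_contingency"] = res.contingency.tolist()
                st.info[f"{key}_fisher_p"] = res.fisher_p
                st.info[f"{key}_distance_mwu"] = {
                    "U": res.U, "p": res.mwu_p,
                    "median_attenuated_mm": res.median_attenuated,
                    "median_nonattenuated_mm": res.median_nonattenuated,
                    "n_attenuated": res.n_attenuated,
                    "n_nonattenuated": res.n_nonattenuated,
                }
                rows[f"attenuated_{key}"] = flags
                rows["distance_mm"] = res.distances
            st.info["contingency_definition"] = (
                "rows PreCG/PostCG x columns attenuated/not, over "
                "significant electrodes")
            hio.write_table(pd.DataFrame(rows), self._path("spatial"))

    # ------------------------------------------------------------------- report

    def _warn(self, message: str):
        logger.warning(message)
        self.report["warnings"].append(message)

    def finalize(self) -> dict:
        """Assemble counts, write config echo and report.json."""
        s = self.report["summary"]
        if self.electrodes is not None:
            s["electrodes_total"] = len(self.electrodes)
            s["electrodes_included"] = int((~self.electrodes.ground).sum())
            s["electrodes_roi"] = int((self.electrodes.in_roi
                                       & ~self.electrodes.ground).sum())
        if self.significance is not None:
            n_sig = self.significance.n_significant
            s["electrodes_significant"] = n_sig
            if self.trials is not None:
                s["pooled_samples_per_trial_position"] = (
                    n_sig * self.trials.n_blocks)
                s["pooled_samples_per_block"] = (
                    n_sig * self.trials.trials_per_block)
        if self.attenuation is not None:
            s["short_term_attenuated"] = self.attenuation.n_short_term
            s["long_term_attenuated"] = self.attenuation.n_long_term
        m = self.report["metadata"]
        m["epoch_indexing"] = "0-based, half-open 100-ms intervals from t=0"
        m["nr_group_samples_per_electrode"] = 30
        m["r_group_samples_per_electrode"] = 27
        m["nr_group_samples_alt_three_per_trial"] = 90
        m["r_group_samples_alt_three_per_trial"] = 81
        for name in ("map", "attenuate", "spatial"):
            if name not in self.report["stages"]:
                self.report["stages"][name] = {"status": "skipped"}
        self.cfg.to_yaml(self._path("config"))
        hio.write_report(self.report, self._path("report"))
        return self.report


class _StageContext:
    """Stage bracket: timing/logging plus error wrapping with stage name."""

    def __init__(self, pipe: Pipeline, name: str):
        self.pipe, self.name = pipe, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        self.info = {}
        self.pipe.report["stages"][self.name] = self.info
        self.info["status"] = "running"
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            if self.info.get("status") == "running":
                self.info["status"] = "done"
            logger.info("stage %s: done in %.2f s", self.name, dt)
            return False
        self.info["status"] = "failed"
        logger.error("stage %s failed after %.2f s: %s", self.name, dt, exc)
        if isinstance(exc, HgaMapError) and not isinstance(exc, PipelineError):
            err = PipelineError(self.name, str(exc))
            err.exit_code = exc.exit_code
            raise err from exc
        return False


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / FILES["log"], mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return the run report.

    Identical configuration and seed produce a byte-identical report.
    """
    pipe = Pipeline(config)
    handler = _setup_logging(pipe.out)
    try:
        pipe.acquire()
        pipe.run_preprocess()
        if config.stages.get("map", True):
            pipe.run_map()
            if config.stages.get("attenuate", True):
                pipe.run_attenuate()
                if config.stages.get("spatial", True):
                    pipe.run_spatial()
        return pipe.finalize()
    finally:
        logger.removeHandler(handler)
        handler.close()
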