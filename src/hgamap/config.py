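"""Run configuration: every numeric default of the paradigm and signal chain
is a named key, so deviations from the standard protocol are explicit."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import yaml

from .errors import ConfigError
from .paradigm import ParadigmSpec
from .synthio import DEFAULT_SIGMA

_KNOWN_KEYS = {
    "output_dir", "seed", "simulate", "recording", "recording_format",
    "events", "electrodes", "paradigm", "synthetic", "correction_scope",
    "alpha", "sigma", "default_hemisphere", "stages", "write_recording",
}

_STAGES = ("map", "attenuate", "spatial")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``synthetic`` holds keyword overrides for :class:`~hgamap.synthio.
    SyntheticConfig` (its seed always follows ``seed``); ``stages`` toggles
    the analysis stages after preprocessing.
    """

    output_dir: str = "hgamap_out"
    seed: int = 0
    simulate: bool = True
    recording: Optional[str] = None
    recording_format: str = "auto"
    events: Optional[str] = None
    electrodes: Optional[str] = None
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    synthetic: Dict = field(default_factory=dict)
    correction_scope: str = "all"
    alpha: float = 0.05
    sigma: Dict = field(default_factory=lambda: {
        h: list(v) for h, v in DEFAULT_SIGMA.items()})
    default_hemisphere: str = "left"
    stages: Dict[str, bool] = field(default_factory=dict)
    write_recording: bool = False

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if self.correction_scope not in ("all", "roi"):
            raise ConfigError("correction_scope must be 'all' or 'roi'")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.default_hemisphere not in ("left", "right"):
            raise ConfigError("default_hemisphere must be 'left' or 'right'")
        for hemi in ("left", "right"):
            if hemi not in self.sigma or len(self.sigma[hemi]) != 3:
                raise ConfigError(f"sigma['{hemi}'] must be [x, y, z] in mm")
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ConfigError(f"unknown stage toggles {sorted(bad)}; "
                              f"known: {_STAGES}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in _STAGES}
        if not self.simulate:
            missing = [k for k in ("recording", "events", "electrodes")
                       if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"simulate is off but {missing} paths are "
                                  "not set")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys {sorted(unknown)}")
        doc = dict(doc)
        if "paradigm" in doc and isinstance(doc["paradigm"], dict):
            try:
                doc["paradigm"] = ParadigmSpec(**doc["paradigm"])
            except TypeError as err:
                raise ConfigError(f"bad paradigm section: {err}") from None
        try:
            return cls(**doc)
        except TypeError as err:
            raise ConfigError(str(err)) from None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(doc)

    def to_dict(self, include_output_dir: bool = True) -> dict:
        doc = asdict(self)
        doc["paradigm"] = asdict(self.paradigm)
        if not include_output_dir:
            doc.pop("output_dir")
        return doc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
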