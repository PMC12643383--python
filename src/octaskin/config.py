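"""Run configuration: every tunable of the toolkit under namespaced keys.

Defaults reproduce the reference pipeline settings: discard 30 B-scans,
90-slice depth crop, Frangi scales 4:2:8 with alpha 0.01 and beta 1,
100-voxel minimum component size, CAL radii alpha=2/beta=3, box counting
with 20 scales and 5 offsets, 99th-percentile projection clipping.
Unknown keys are rejected so a typo never silently falls back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enface import BandSpec, MaskGenParams
from .metrics import BoxCountParams, CALParams
from .phantom import PhantomSpec
from .preprocess import EnhanceParams, FrangiParams, PAFilterParams, PipelineConfig

__all__ = ["FlattenParams", "RunConfig", "load_config", "dump_config"]


@dataclass
class FlattenParams:
    """Surface flattening: frames to discard and output depth."""

    discard_bscans: int = 30
    out_depth: int = 90
    threshold_frac: float = 0.5


@dataclass
class RunConfig:
    """All module parameters merged under namespaced sections."""

    flatten: FlattenParams = field(default_factory=FlattenParams)
    pa_filter: PAFilterParams = field(default_factory=PAFilterParams)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    band: BandSpec = field(default_factory=BandSpec)
    maskgen: MaskGenParams = field(default_factory=MaskGenParams)
    cal: CALParams = field(default_factory=CALParams)
    boxcount: BoxCountParams = field(default_factory=BoxCountParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    clip_percentile: float = 99.0
    seed: int = 0
    log_level: str = "INFO"

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(pa_filter=self.pa_filter, enhance=self.enhance,
                              frangi=self.frangi)

    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                d = dataclasses.asdict(v)
                for k, val in d.items():
                    if isinstance(val, tuple):
                        d[k] = list(val)
                out[f.name] = d
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        known = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current):
                sub_known = {f.name for f in dataclasses.fields(current)}
                if not isinstance(value, dict):
                    raise TypeError(f"config section {key!r} must be a mapping")
                kwargs = {}
                for sk, sv in value.items():
                    if sk not in sub_known:
                        raise KeyError(f"unknown config key {key}.{sk!r}")
                    kwargs[sk] = tuple(sv) if isinstance(sv, list) else sv
                merged = dataclasses.replace(current, **kwargs)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg


def load_config(path) -> RunConfig:
    """Read a YAML config file, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig) -> str:
    """Serialize a config to YAML (round-trips through load)."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
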