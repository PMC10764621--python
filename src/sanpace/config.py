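"""Declarative run configuration with strict schema validation.

A run config is a nested key/value mapping (YAML on disk).  Every section
maps onto one of the package's frozen config/ground-truth dataclasses;
unknown keys anywhere are rejected before any computation, and every
threshold in effect is echoed into the output MANIFEST.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ap_features import APConfig
from .dose_response import WindowConfig
from .hrv import EpisodeConfig, SpectralBands
from .synth import APGroundTruth, DrugEffectSpec, GeneTableGroundTruth, \
    RRGroundTruth

__all__ = ["RunConfig", "load_config"]

_KNOWN_STAGES = ("synth_ap", "synth_rr", "synth_genes", "ap", "dose",
                 "hrv", "genes")


def _build(cls, mapping: dict | None, section: str):
    """Instantiate a config dataclass from a mapping, rejecting unknown
    keys with the offending section/key named."""
    mapping = dict(mapping or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section "
            f"{section!r}; allowed: {sorted(allowed)}")
    for key, val in mapping.items():
        if isinstance(val, list):  # YAML lists -> hashable tuples
            mapping[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in val)
    return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    """Validated whole-pipeline configuration."""

    stages: tuple[str, ...] = ("synth_ap", "ap")
    seed: int = 0
    out_dir: str = "sanpace_out"
    duration_s: float = 30.0
    sampling_rate_hz: float = 10_000.0
    concentration: float | None = None
    fdr: float = 0.05
    ap: APConfig = field(default_factory=APConfig)
    dose: WindowConfig = field(default_factory=WindowConfig)
    bands: SpectralBands = field(default_factory=SpectralBands)
    episodes: EpisodeConfig = field(default_factory=EpisodeConfig)
    synth_ap: APGroundTruth = field(default_factory=APGroundTruth)
    synth_drug: DrugEffectSpec | None = None
    synth_rr: RRGroundTruth = field(default_factory=RRGroundTruth)
    synth_genes: GeneTableGroundTruth = field(
        default_factory=GeneTableGroundTruth)

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}; "
                                 f"allowed: {list(_KNOWN_STAGES)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw or {})
        sections = {
            "ap": APConfig, "dose": WindowConfig, "bands": SpectralBands,
            "episodes": EpisodeConfig, "synth_ap": APGroundTruth,
            "synth_drug": DrugEffectSpec, "synth_rr": RRGroundTruth,
            "synth_genes": GeneTableGroundTruth,
        }
        kwargs: dict[str, Any] = {}
        for name, sub_cls in sections.items():
            if name in raw:
                sub = raw.pop(name)
                kwargs[name] = None if sub is None else \
                    _build(sub_cls, sub, name)
        if "stages" in raw:
            kwargs["stages"] = tuple(raw.pop("stages"))
        scalars = {f.name for f in dataclasses.fields(cls)} - set(sections) \
            - {"stages"}
        unknown = set(raw) - scalars
        if unknown:
            raise ValueError(f"unknown top-level config key(s) "
                             f"{sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        """Full effective configuration (all thresholds echoed)."""
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)
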