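"""Pipeline configuration: namespaced, strictly validated, fully resolvable.

Every stage's parameters live under a namespaced section (synth.*, detect.*,
track.*, geometry.*, quantify.*, stats.*).  Unknown keys are rejected before
any computation, and every run writes the fully resolved configuration next
to its outputs so that each artifact is reproducible from that file alone.
Units are micrometres and minutes throughout; image coordinates have their
origin at the top-left corner with y increasing downward.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .synthgen import ConfigurationError, LabelSpec, MotionSpec, OrganoidSpec, RenderSpec


def _from_mapping(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SynthConfig:
    organoid: OrganoidSpec = field(default_factory=OrganoidSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    labels: LabelSpec = field(default_factory=LabelSpec)
    render: RenderSpec = field(default_factory=RenderSpec)
    ablate_k: int = 0              # 0 = control (no ablation)
    ablation_frame: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        data = dict(data)
        parts = {}
        for key, sub in (("organoid", OrganoidSpec), ("motion", MotionSpec),
                         ("labels", LabelSpec), ("render", RenderSpec)):
            if key in data:
                raw = dict(data.pop(key))
                if key == "labels" and "bin_boosts" in raw:
                    raw["bin_boosts"] = {int(k): float(v)
                                         for k, v in raw["bin_boosts"].items()}
                parts[key] = _from_mapping(sub, raw, f"synth.{key}")
        return _from_mapping(cls, {**data, **parts}, "synth")


@dataclass(frozen=True)
class DetectConfig:
    channel: int = 0
    projection_mode: str = "max"
    sigma_um: float = 1.0
    min_separation_um: float = 2.0
    rel_threshold: float = 0.15
    aperture_um: float = 0.0       # 0 = use the detection radius
    exclusion_radius_um: float = 0.0


@dataclass(frozen=True)
class TrackConfig:
    max_link_um: float = 15.0
    max_gap_frames: int = 2
    min_duration_frac: float = 0.5


@dataclass(frozen=True)
class GeometryConfig:
    bin_width_um: float = 30.0
    distance_metric: str = "arc"   # 'chord' available as a sensitivity option
    refine_geometric: bool = False


@dataclass(frozen=True)
class QuantifyConfig:
    edu_threshold_strategy: str = "otsu"
    edu_fixed_value: float = 0.0
    edu_mad_k: float = 3.0
    migration_metric: str = "path_length_um"
    reference_frame: int = 0
    smooth_sigma_um: float = 2.0
    closing_radius_um: float = 10.0


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    holm_adjust: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "orgwound_out"
    ablation_site_xy_um: tuple[float, float] | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        parts = {}
        if "synth" in data:
            parts["synth"] = SynthConfig.from_dict(dict(data.pop("synth")))
        for key, sub in (("detect", DetectConfig), ("track", TrackConfig),
                         ("geometry", GeometryConfig), ("quantify", QuantifyConfig),
                         ("stats", StatsConfig)):
            if key in data:
                parts[key] = _from_mapping(sub, dict(data.pop(key)), key)
        if data.get("ablation_site_xy_um") is not None:
            data["ablation_site_xy_um"] = tuple(data["ablation_site_xy_um"])
        return _from_mapping(cls, {**data, **parts}, "top level")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            if hasattr(obj, "item"):
                return obj.item()
            return obj
        return convert(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_override(self, dotted_key: str, value) -> "PipelineConfig":
        """Apply a single 'section.key=value' override (YAML-parsed value)."""
        data = self.to_dict()
        node = data
        *head, last = dotted_key.split(".")
        for part in head:
            if part not in node or not isinstance(node[part], dict):
                raise ConfigurationError(f"unknown config section '{part}'")
            node = node[part]
        if last not in node:
            raise ConfigurationError(f"unknown config key '{dotted_key}'")
        node[last] = yaml.safe_load(str(value))
        return PipelineConfig.from_dict(data)
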