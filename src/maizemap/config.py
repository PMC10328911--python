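"""Run configuration: a versioned YAML schema covering every stage.

A run is reproducible from (config, seed) alone; every tunable of the
simulator, compositing, classifier and postprocessing stages appears as a
named key with its default.  Dotted-path overrides (``classifier.epochs=50``)
are applied after the file is read and before validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .classifier import ClassifierConfig
from .simulate import SimScenario

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


@dataclass
class SamplingConfig:
    n_per_class: int = 400
    train_fraction: float = 0.7


@dataclass
class CompositingConfig:
    max_cloud_fraction: float = 0.8
    use_indices: bool = False      # ablation: stack NDVI/EVI/NDWI per period


@dataclass
class PostprocessConfig:
    min_patch_px: int = 4
    mask_schedule: dict[int, str] = field(default_factory=dict)


@dataclass
class ReferenceConfig:
    error_sd: float = 0.05


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    output_dir: str = "runs/default"
    scenario: SimScenario = field(default_factory=SimScenario)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    compositing: CompositingConfig = field(default_factory=CompositingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")
        try:
            self.scenario.validate()
            self.classifier.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
        s = self.sampling
        if not (0.0 < s.train_fraction < 1.0):
            raise ConfigError("sampling.train_fraction must be in (0, 1)")
        if s.n_per_class < 10:
            raise ConfigError("sampling.n_per_class must be >= 10")
        c = self.compositing
        if not (0.0 <= c.max_cloud_fraction <= 1.0):
            raise ConfigError("compositing.max_cloud_fraction must be in [0, 1]")
        if self.postprocess.min_patch_px < 1:
            raise ConfigError("postprocess.min_patch_px must be >= 1")
        if self.reference.error_sd < 0:
            raise ConfigError("reference.error_sd must be >= 0")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj
        return listify(asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(dc_type, data):
            if not isinstance(data, dict):
                raise ConfigError(f"expected mapping for {dc_type.__name__}, got {data!r}")
            known = {f.name: f for f in fields(dc_type)}
            unknown = set(data) - set(known)
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} in {dc_type.__name__}")
            kwargs = {}
            for name, value in data.items():
                f = known[name]
                if is_dataclass(f.type) or f.type in _SECTION_TYPES:
                    kwargs[name] = build(_SECTION_TYPES.get(f.type, f.type), value)
                else:
                    kwargs[name] = _coerce(name, value)
            return dc_type(**kwargs)

        cfg = build(cls, raw or {})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from None
        return cls.from_dict(raw or {})

    def with_overrides(self, overrides: dict[str, object]) -> "RunConfig":
        """Apply dotted-path overrides and re-validate."""
        raw = self.to_dict()
        for dotted, value in overrides.items():
            node = raw
            *parents, leaf = dotted.split(".")
            for p in parents:
                if p not in node or not isinstance(node[p], dict):
                    raise ConfigError(f"unknown config section {p!r} in {dotted!r}")
                node = node[p]
            if leaf not in node:
                raise ConfigError(f"unknown config key {dotted!r}")
            node[leaf] = value
        return type(self).from_dict(raw)


_SECTION_TYPES = {t.__name__: t for t in
                  (SimScenario, SamplingConfig, CompositingConfig,
                   ClassifierConfig, PostprocessConfig, ReferenceConfig)}


_TUPLE_KEYS = {"grid_shape", "class_fractions", "head_dims"}


def _coerce(name: str, value):
    if name in _TUPLE_KEYS and isinstance(value, (list, tuple)):
        return tuple(value)
    if name == "mask_schedule" and isinstance(value, dict):
        return {int(k): str(v) for k, v in value.items()}
    return value


def parse_override(text: str) -> tuple[str, object]:
    """Parse a ``key=value`` CLI override; values go through YAML parsing."""
    if "=" not in text:
        raise ConfigError(f"override {text!r} must look like key=value")
    key, _, raw = text.partition("=")
    return key.strip(), yaml.safe_load(raw)
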