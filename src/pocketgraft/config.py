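"""Tool configuration: one YAML/JSON document covering every stage.

Unknown keys are rejected so typos fail loudly.  The library defaults are
the per-stage method defaults; the ``case-study`` preset mirrors the
parameter set used for mining pockets from an alpha-alpha superhelix
structure collection (distance factor 2.0, orientation factors 1.0,
variance threshold effectively disabled).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .atlas import AtlasParams, InteractionRadii
from .errors import ConfigError
from .geometry import SimilarityWeights
from .grafting import GraftingParams
from .pockets import ClusteringParams, MiningParams
from .structures import PreprocessParams

LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class ToolConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    atlas: AtlasParams = field(default_factory=AtlasParams)
    similarity: SimilarityWeights = field(default_factory=SimilarityWeights)
    mining: MiningParams = field(default_factory=MiningParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    grafting: GraftingParams = field(default_factory=GraftingParams)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.log_level not in LOG_LEVELS:
            raise ConfigError(f"log_level must be one of {LOG_LEVELS}")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            return obj
        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "preprocess": PreprocessParams,
    "atlas": AtlasParams,
    "similarity": SimilarityWeights,
    "mining": MiningParams,
    "clustering": ClusteringParams,
    "grafting": GraftingParams,
}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "radii":
            value = _build_section(InteractionRadii, value, f"{path}.radii")
        elif key == "weights":
            value = _build_section(SimilarityWeights, value, f"{path}.weights")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(data: dict) -> ToolConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = set(_SECTION_TYPES) | {"seed", "log_level"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build_section(cls, data[section], section)
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = data["seed"]
    if "log_level" in data:
        kwargs["log_level"] = data["log_level"]
    cfg = ToolConfig(**kwargs)
    # shared weights: similarity block applies everywhere unless a stage
    # sets its own
    if "similarity" in data:
        if "clustering" not in data or "weights" not in data["clustering"]:
            cfg.clustering.weights = cfg.similarity
        if "grafting" not in data or "weights" not in data["grafting"]:
            cfg.grafting.weights = cfg.similarity
    if "seed" in data and ("clustering" not in data
                           or "seed" not in data["clustering"]):
        cfg.clustering.seed = cfg.seed
    return cfg


def load_config(path: str | Path) -> ToolConfig:
    """Load YAML (or JSON — valid YAML) configuration."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def case_study_preset() -> ToolConfig:
    """Parameter set of the reference case-study mining run on an
    alpha-alpha superhelix structure collection: distance factor 2.0,
    orientation factors 1.0, noise reduction disabled (variance threshold
    9999)."""
    w = SimilarityWeights(fd=2.0, fo=1.0, fs=1.0)
    return ToolConfig(
        preprocess=PreprocessParams(max_contact_distance=8.0,
                                    min_binder_length=40,
                                    min_ligand_length=3),
        atlas=AtlasParams(),
        similarity=w,
        mining=MiningParams(support_threshold=0.01,
                            confidence_threshold=0.02,
                            min_pocket_size=3,
                            max_pockets_per_ligand_type=10,
                            cardinality_base=1.21),
        clustering=ClusteringParams(variance_threshold=9999.0, weights=w),
        grafting=GraftingParams(weights=w),
    )


PRESETS = {"case-study": case_study_preset}


def get_preset(name: str) -> ToolConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
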