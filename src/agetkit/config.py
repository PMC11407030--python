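"""Run configuration: nested per-stage sections, one global seed.

Unknown keys are rejected so a typo cannot silently fall back to a default;
every command writes a fully-resolved snapshot of the config it actually ran
with next to its outputs.  All randomness derives from the global seed via
named per-module substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .inference import LikelihoodSpec, MCMCConfig, PriorSpec
from .synthetic import SyntheticConfig, hash_stream


class ConfigError(ValueError):
    pass


@dataclass
class ProcessingConfig:
    threshold_percentile: float = 20.0
    window: int = 11
    polyorder: int = 3
    n_bins: int = 50


@dataclass
class AlignConfig:
    max_iterations: int = 50
    normal_k: int = 20
    rms_threshold_fraction: float = 0.05  # of target A-P length
    max_correspondence_fraction: float = 0.1
    min_inlier_fraction: float = 0.5


@dataclass
class BuildConfig:
    n_neighbors: int = 5
    method: str = "median"
    min_sources: int = 3


@dataclass
class ModelConfig:
    total_span: float = 1.0
    substeps: int = 10


@dataclass
class ClusterConfig:
    k: int | None = None  # None = choose from the WSS elbow
    k_min: int = 2
    k_max: int = 15
    min_cluster_fraction: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    build: BuildConfig = field(default_factory=BuildConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    fit: MCMCConfig = field(default_factory=MCMCConfig)
    likelihood: LikelihoodSpec = field(default_factory=LikelihoodSpec)
    prior: PriorSpec = field(default_factory=PriorSpec)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def substream_seed(self, stream: str) -> int:
        return (self.seed * 1_000_003 + hash_stream(stream)) % (2**31)


def _build(cls, doc: dict, path: str):
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(doc) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in doc.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[name] = _build(f.type, value, f"{path}.{name}")
        elif isinstance(value, dict):
            # nested dataclass referenced by name (from __future__ annotations)
            sub = _SECTION_TYPES.get(name)
            if sub is None:
                raise ConfigError(f"{path}.{name}: unexpected mapping")
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


_SECTION_TYPES = {
    "synth": SyntheticConfig,
    "processing": ProcessingConfig,
    "align": AlignConfig,
    "build": BuildConfig,
    "model": ModelConfig,
    "fit": MCMCConfig,
    "likelihood": LikelihoodSpec,
    "prior": PriorSpec,
    "cluster": ClusterConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    return _build(RunConfig, doc, "config")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def snapshot_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved config next to a command's outputs."""
    Path(path).write_text(json.dumps(_to_plain(config), indent=2, default=str) + "\n")
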