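"""YAML pipeline configuration: a single validated source of truth for all
paths, thresholds and seeds.  Unknown keys are rejected by name."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .nn import TrainingConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class ActivityParams:
    upstream: int = 3000
    downstream: int = 3000
    per_cell: bool = False


@dataclass
class FilterParams:
    min_cells: int = 0


@dataclass
class SplitParams:
    train_frac: float = 0.9
    seed: int = 0


@dataclass
class ClusterParams:
    min_size: int | None = None
    max_size: int | None = None
    n_clusters: int | None = None
    seed: int = 0


@dataclass
class NetworkParams:
    rounds: int = 5
    top_k: int = 50


@dataclass
class InputPaths:
    peaks: str | None = None
    sites_dir: str | None = None
    genes: str | None = None
    expression: str | None = None
    velocity: str | None = None
    peak_cell_matrix: str | None = None
    truth: str | None = None


@dataclass
class PipelineConfig:
    inputs: InputPaths = field(default_factory=InputPaths)
    output_dir: str = "velogrn_out"
    activity: ActivityParams = field(default_factory=ActivityParams)
    filters: FilterParams = field(default_factory=FilterParams)
    split: SplitParams = field(default_factory=SplitParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    network: NetworkParams = field(default_factory=NetworkParams)


_SECTIONS = {
    "inputs": InputPaths,
    "activity": ActivityParams,
    "filters": FilterParams,
    "split": SplitParams,
    "clustering": ClusterParams,
    "training": TrainingConfig,
    "network": NetworkParams,
}


def _build_section(cls, data: dict, section: str):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )
    if cls is TrainingConfig and "share_layers" in data:
        data = {**data, "share_layers": tuple(data["share_layers"])}
    return cls(**data)


def load_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a YAML config file (or an already-parsed dict);
    defaults are filled in, unknown keys rejected."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known_top = set(_SECTIONS) | {"output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        data = raw.get(section, {}) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, data, section)
    return PipelineConfig(output_dir=raw.get("output_dir", "velogrn_out"), **kwargs)


def dump_config(config: PipelineConfig) -> str:
    d = asdict(config)
    d["training"]["share_layers"] = list(d["training"]["share_layers"])
    return yaml.safe_dump(d, sort_keys=True)
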