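"""Run configuration: one YAML file drives every CLI command.

The schema mirrors the dataclasses it feeds (phantom spec, network config,
training schedule, region-growing and mean-teacher knobs).  Every command
echoes the fully-resolved config into its output directory so runs are
reproducible from the artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import NetworkConfig
from .phantom import PhantomSpec
from .preprocess import RegionGrowConfig
from .semisupervised import MeanTeacherConfig
from .train import TrainConfig
from .mgam import ALPHA_GRID


@dataclass
class RunConfig:
    seed: int = 0
    n_train: int = 200
    n_val: int = 40
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    region_grow: RegionGrowConfig = field(default_factory=RegionGrowConfig)
    mean_teacher: MeanTeacherConfig = field(default_factory=MeanTeacherConfig)
    alpha_grid: tuple = ALPHA_GRID

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_grid"] = [list(a) for a in self.alpha_grid]
        return d


_SECTIONS = {"phantom": PhantomSpec, "network": NetworkConfig,
             "training": TrainConfig, "region_grow": RegionGrowConfig,
             "mean_teacher": MeanTeacherConfig}

_TUPLE_FIELDS = {"image_size", "semi_axis_range"}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from YAML (all keys optional) plus overrides."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            sec = {k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in val.items()}
            kwargs[key] = _SECTIONS[key](**sec)
        elif key == "alpha_grid":
            kwargs[key] = tuple(tuple(a) for a in val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
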