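"""Run configuration: YAML loading, validation and defaults.

A minimal config is ``{experiment: I, group: DP, seed: 1}``; every model
parameter can be overridden in the named blocks ``perception``, ``map``,
``strategies`` and ``protocol``.  Unknown keys are rejected by name.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .perception import PerceptionParams
from .cognitive_map import MapParams
from .experiments import (StrategyParams, ProtocolParams, EXPERIMENTS, GROUPS,
                          DEFAULT_RATES, DEFAULT_GATING_GAMMA)

_VI_CONDITIONS = ("Session-Same", "Session-Diff", "Trial-Same", "Trial-Diff")


@dataclass
class RunConfig:
    experiment: str
    group: str
    seed: int
    condition: str = ""
    n_repeats: int = 50
    log_proposals: bool = False
    log_steps: bool = False
    outdir: str = "results"
    perception: PerceptionParams = field(default_factory=PerceptionParams)
    map: MapParams = field(default_factory=MapParams)
    strategies: StrategyParams = None  # type: ignore[assignment]
    protocol: ProtocolParams = field(default_factory=ProtocolParams)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.experiment == "VI" and self.condition not in _VI_CONDITIONS:
            raise ValueError(
                f"experiment VI needs condition in {_VI_CONDITIONS}")
        if self.strategies is None:
            eta_d, eta_g = DEFAULT_RATES[self.experiment]
            self.strategies = StrategyParams(
                eta_direction=eta_d, eta_gating=eta_g,
                gamma_gating=DEFAULT_GATING_GAMMA.get(self.experiment, 0.9))


_BLOCKS = {"perception": PerceptionParams, "map": MapParams,
           "strategies": StrategyParams, "protocol": ProtocolParams}


def _build_block(cls, data: dict, block: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {block!r} block: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in data:
        raise ValueError("config must set a seed (mandatory for reproducibility)")
    for block, cls in _BLOCKS.items():
        if block in data and isinstance(data[block], dict):
            data[block] = _build_block(cls, data[block], block)
    return RunConfig(**data)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    out = {}
    for f in dataclasses.fields(RunConfig):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v):
            v = {kf.name: (list(kv) if isinstance(kv := getattr(v, kf.name), tuple)
                           else kv)
                 for kf in dataclasses.fields(v)}
        out[f.name] = v
    return out


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
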