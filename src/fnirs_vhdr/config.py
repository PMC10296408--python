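"""Run configuration: one validated, serializable object for a full run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass

import yaml

from .metrics import DEFAULT_BASELINE, DEFAULT_POST_S, DEFAULT_PRE_S, DEFAULT_SEARCH
from .preprocess import PreprocessParams
from .simulate import KernelParams, SimulationConfig, asd_default_config, td_default_config
from .stats import StatsConfig


@dataclass
class ScheduleConfig:
    n_stim: int = 20
    n_mock: int = 20
    on_s: float = 5.0
    off_s: float = 10.0

    def __post_init__(self):
        if self.n_stim < 0 or self.n_mock < 0:
            raise ValueError("trial counts must be non-negative")
        if self.on_s <= 0 or self.off_s <= 0:
            raise ValueError("trial durations must be positive")


@dataclass
class WindowConfig:
    pre_s: float = DEFAULT_PRE_S
    post_s: float = DEFAULT_POST_S
    baseline: tuple[float, float] = DEFAULT_BASELINE
    search: tuple[float, float] = DEFAULT_SEARCH

    def __post_init__(self):
        self.baseline = tuple(self.baseline)
        self.search = tuple(self.search)
        b0, b1 = self.baseline
        if not (-self.pre_s <= b0 < b1 <= 0):
            raise ValueError("baseline window must lie within [-pre_s, 0]")


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate→preprocess→analyze→stats run."""

    montage: str = "default"
    n_td: int = 13
    n_asd: int = 12
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    sim_td: SimulationConfig = field(default_factory=td_default_config)
    sim_asd: SimulationConfig = field(default_factory=asd_default_config)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    windows: WindowConfig = field(default_factory=WindowConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    save_recordings: bool = False

    def __post_init__(self):
        if self.montage != "default":
            raise ValueError("only the built-in default montage is available")
        if self.n_td < 1 or self.n_asd < 1:
            raise ValueError("both groups need at least one subject")


def _from_dict(cls, data):
    if not is_dataclass(cls):
        return data
    kwargs = {}
    type_map = {f.name: f.type for f in fields(cls)}
    nested = {
        "schedule": ScheduleConfig, "sim_td": SimulationConfig,
        "sim_asd": SimulationConfig, "preprocess": PreprocessParams,
        "windows": WindowConfig, "stats": StatsConfig, "kernel": KernelParams,
    }
    for key, value in data.items():
        if key not in type_map:
            raise ValueError(f"unknown configuration key {key!r} for {cls.__name__}")
        if key in nested and isinstance(value, dict):
            value = _from_dict(nested[key], value)
        elif key == "dpf" and isinstance(value, dict):
            value = {float(k): float(v) for k, v in value.items()}
        elif key in ("groups", "conditions", "baseline", "search", "age_range_years") and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _listify(asdict(config))


def config_from_dict(data: dict) -> RunConfig:
    return _from_dict(RunConfig, data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
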