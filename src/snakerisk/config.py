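"""Pipeline configuration: YAML/JSON loading, defaulting, validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .disease_mapping import McmcConfig, ModelPriors
from .risk_overlay import HabitatRule
from .smoothing_eval import DEFAULT_SPLITS
from .synthetic_world import WorldConfig
from .travel_time import SpeedModel

__all__ = ["PipelineConfig", "load_config", "validate_config"]

PAPER_SCALE_ITERATIONS = 50000


def _default_world() -> WorldConfig:
    # desk-scale world: 64 districts, 18 km x 18 km raster at 150 m cells
    # (coarser than the study's 30 m so all travel-time categories appear),
    # 18 years of counts at a country-scale base rate
    return WorldConfig(
        lattice_rows=8, lattice_cols=8, raster_rows=120, raster_cols=120,
        cell_size=150.0, n_years=18, base_rate_per_100k=25.0, sigma_u=0.4,
        population_range=(500, 20000),
    )


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=_default_world)
    priors: ModelPriors = field(default_factory=ModelPriors)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    eval_mcmc: McmcConfig = field(
        default_factory=lambda: McmcConfig(n_burn=500, n_keep=500, n_chains=1)
    )
    habitat: HabitatRule = field(default_factory=HabitatRule)
    speed: SpeedModel = field(default_factory=SpeedModel)
    incidence_threshold: float = 30.0  # per 100,000 per year
    exceedance_cutoff: float = 0.10
    time_category_bounds: tuple = (2.0, 3.0)  # hours
    buffer_radius_m: float = 2000.0
    fit_window_years: int = 5  # most recent years used for the risk fit
    splits: dict = field(default_factory=lambda: dict(DEFAULT_SPLITS))
    seed: int = 0

    def __post_init__(self) -> None:
        validate_config(self)


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    if cfg.incidence_threshold <= 0:
        raise ValueError("incidence_threshold must be > 0")
    if not 0.0 <= cfg.exceedance_cutoff <= 1.0:
        raise ValueError(
            f"exceedance_cutoff must lie in [0, 1], got {cfg.exceedance_cutoff}"
        )
    lo, hi = cfg.time_category_bounds
    if not lo < hi:
        raise ValueError(
            f"time_category_bounds must be increasing, got ({lo}, {hi})"
        )
    if cfg.buffer_radius_m <= 0:
        raise ValueError("buffer_radius_m must be > 0")
    if cfg.fit_window_years < 1 or cfg.fit_window_years > cfg.world.n_years:
        raise ValueError("fit_window_years must be in [1, world.n_years]")
    return cfg


_SECTION_TYPES = {
    "world": WorldConfig,
    "priors": ModelPriors,
    "mcmc": McmcConfig,
    "eval_mcmc": McmcConfig,
    "habitat": HabitatRule,
    "speed": SpeedModel,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in '{path}': {sorted(unknown)}")
    kwargs = dict(data)
    # YAML gives lists where dataclasses expect tuples/frozensets
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            if f.name == "suitable_biotic_units":
                kwargs[f.name] = frozenset(kwargs[f.name])
            else:
                kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def _parse_splits(data: dict) -> dict:
    out = {}
    for key, pairs in data.items():
        out[int(key)] = [
            ((int(p[0][0]), int(p[0][1])), (int(p[1][0]), int(p[1][1])))
            for p in pairs
        ]
    return out


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML (or JSON) config; missing keys default.

    Unknown keys raise. ``path=None`` or an empty file yields defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping: {path}")
        data = loaded
    if overrides:
        data = {**data, **overrides}

    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs = {}
    for name, value in data.items():
        if name in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build_section(_SECTION_TYPES[name], value, name)
        elif name == "splits":
            kwargs[name] = _parse_splits(value)
        elif name == "time_category_bounds":
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(cfg), fh, indent=1, default=str)
        fh.write("\n")
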