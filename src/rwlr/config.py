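"""Typed, defaulted, range-checked run configuration.

Defaults follow the source analysis where it states a value (dry spells of
at least 5 days, |r| > 0.70 collinearity threshold, 1-pixel buffer width,
April–September growing season) and the package's documented decisions
elsewhere.  Unknown keys are rejected with a nearest-match suggestion.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from rwlr.errors import ConfigError

__all__ = ["RunConfig", "validate_config", "ALL_STAGES"]

ALL_STAGES = ["simulate", "tvdi", "rwlr", "rank", "sem", "karst"]


@dataclass
class RunConfig:
    # run control
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "runs/default"
    log_level: str = "INFO"
    # external inputs (optional when the simulate stage is enabled)
    precip_csv: str | None = None
    czu_csv: str | None = None
    # precipitation generator
    n_days: int = 1096
    p_wet_to_wet: float = 0.60
    p_dry_to_wet: float = 0.25
    mean_depth: float = 8.0
    # scene generator
    leakage: float = 0.05
    et_rate: float = 0.02
    noise_sd: float = 0.0
    scene_rows: int = 24
    scene_cols: int = 24
    composite_interval: int = 5
    # triangle edges
    n_bins: int = 20
    edge_percentile: float = 1.0
    min_pixels_per_bin: int = 5
    ndvi_min: float = 0.05
    # dry spells / water-loss rate
    min_length: int = 5
    wet_threshold: float = 0.0
    aggregate: str = "mean"
    min_composites: int = 2
    czu_radius: float = 10.0
    # covariate table
    n_czu: int = 23
    czu_noise_sd: float = 1.0
    # variable importance
    collinearity_threshold: float = 0.70
    # karst signal
    buffer_width: int = 1
    connectivity: int = 8
    grid_rows: int = 40
    grid_cols: int = 40
    grid_years: int = 30
    r_inside: float = -0.2
    r_outside: float = 0.3
    growing_months: list[int] = field(default_factory=lambda: [4, 5, 6, 7, 8, 9])

    def validate(self) -> "RunConfig":
        checks = [
            (self.min_length >= 2, "min_length must be >= 2"),
            (self.min_composites >= 2, "min_composites must be >= 2"),
            (0 < self.p_wet_to_wet <= 1, "p_wet_to_wet must lie in (0, 1]"),
            (0 < self.p_dry_to_wet <= 1, "p_dry_to_wet must lie in (0, 1]"),
            (self.n_days >= 365, "n_days must be >= 365"),
            (0.5 < self.edge_percentile <= 1.0,
             "edge_percentile must lie in (0.5, 1]"),
            (self.n_bins >= 5, "n_bins must be >= 5"),
            (self.aggregate in ("mean", "sum"),
             "aggregate must be 'mean' or 'sum'"),
            (0 < self.collinearity_threshold < 1,
             "collinearity_threshold must lie in (0, 1)"),
            (self.buffer_width >= 0, "buffer_width must be >= 0"),
            (self.connectivity in (4, 8), "connectivity must be 4 or 8"),
            (-1 < self.r_inside < 1, "r_inside must lie in (-1, 1)"),
            (-1 < self.r_outside < 1, "r_outside must lie in (-1, 1)"),
            (self.grid_years >= 10, "grid_years must be >= 10"),
            (self.wet_threshold >= 0, "wet_threshold must be >= 0"),
            (all(s in ALL_STAGES for s in self.stages),
             f"stages must be a subset of {ALL_STAGES}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if "simulate" not in self.stages:
            if "rwlr" in self.stages and self.precip_csv is None:
                raise ConfigError(
                    "precip_csv is required when the simulate stage is disabled"
                )
            if ("rank" in self.stages or "sem" in self.stages) \
                    and self.czu_csv is None:
                raise ConfigError(
                    "czu_csv is required when the simulate stage is disabled"
                )
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(raw: str | dict | Path) -> RunConfig:
    """Parse a YAML config (text, mapping, or path) into a RunConfig.

    Empty input yields all defaults; unknown keys are rejected naming the
    closest valid key; every value is type- and range-checked.
    """
    if isinstance(raw, Path):
        raw = raw.read_text()
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    valid = {f.name: f for f in fields(RunConfig)}
    for key in data:
        if key not in valid:
            close = difflib.get_close_matches(key, valid, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise ConfigError(f"unknown config key {key!r}{hint}")
    cfg = RunConfig(**data)
    # light type coercion guard: ints must not arrive as strings, etc.
    for f in fields(RunConfig):
        val = getattr(cfg, f.name)
        if f.name in ("precip_csv", "czu_csv"):
            if val is not None and not isinstance(val, str):
                raise ConfigError(f"{f.name} must be a path string")
            continue
        if f.type in ("int",) and not isinstance(val, int):
            raise ConfigError(f"{f.name} must be an integer")
        if f.type in ("float",) and not isinstance(val, (int, float)):
            raise ConfigError(f"{f.name} must be a number")
    return cfg.validate()
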