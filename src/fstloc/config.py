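"""Run configuration: YAML schema, validation, seed derivation.

A single human-readable YAML file drives the whole pipeline; the shipped
``data/default.yaml`` holds every default (protocol block lengths, run
counts, aperture geometry, fit grids, ROI thresholds, bias-simulation
grid). Every stochastic stage receives a seed derived deterministically
from the master seed and the stage name, so one integer reproduces a full
study.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .synth import HemisphereConfig, RegionSpec, default_regions

__all__ = ["RunConfig", "load_config", "default_config", "derive_seed"]

REQUIRED_SECTIONS = (
    "seed",
    "noise_sd",
    "hemisphere",
    "schedules",
    "aperture",
    "prf_runs",
    "fit",
    "roi",
    "biassim",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) from the master seed."""
    return int(
        np.random.SeedSequence(
            entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()),)
        ).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunConfig:
    """Validated pipeline configuration with attribute-style access."""

    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_SECTIONS if k not in self.data]
        if missing:
            raise ValueError(f"missing required config field(s): {', '.join(missing)}")
        if not isinstance(self.data["seed"], int):
            raise ValueError("config field 'seed' must be an integer")
        if self.data["noise_sd"] < 0:
            raise ValueError("config field 'noise_sd' must be non-negative")

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def noise_sd(self) -> float:
        return float(self.data["noise_sd"])

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def hemisphere_config(self) -> HemisphereConfig:
        h = self.data["hemisphere"]
        regions = (
            [RegionSpec(**_tupled(r)) for r in h["regions"]]
            if "regions" in h
            else default_regions()
        )
        return HemisphereConfig(
            shape=tuple(h.get("shape", (64, 64))),
            regions=regions,
            background_t1=tuple(h.get("background_t1", (1.331, 0.01))),
            atlas_jitter=int(h.get("atlas_jitter", 2)),
        )

    def grid_spec(self):
        from .prf import GridSpec

        f = self.data["fit"]
        return GridSpec(
            pos_step=float(f.get("pos_step", 1.0)),
            sigma_min=float(f.get("sigma_min", 0.25)),
            sigma_max=float(f.get("sigma_max", 24.0)),
            n_sigma=int(f.get("n_sigma", 20)),
        )

    def replace(self, **updates) -> "RunConfig":
        """New config with top-level fields replaced (nested dicts merged)."""
        data = copy.deepcopy(self.data)
        for key, value in updates.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
        return RunConfig(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))


def _tupled(region_dict: dict) -> dict:
    """YAML lists -> tuples for the (mean, sd) tuning fields."""
    out = dict(region_dict)
    for k, v in out.items():
        if isinstance(v, list):
            out[k] = tuple(v)
    return out


def default_config(seed: int | None = None) -> RunConfig:
    """The shipped default configuration, optionally reseeded."""
    text = resources.files("fstloc").joinpath("data/default.yaml").read_text()
    cfg = RunConfig(yaml.safe_load(text))
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return cfg


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    if path is None:
        return default_config(seed)
    cfg = RunConfig.from_yaml(path)
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return cfg
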