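"""Run configuration: a single TOML file validated against a strict schema.

Unknown keys are rejected (typos fail loudly before any compute) and the
validated config is echoed verbatim into every output artifact together
with its hash, so a run is reconstructible from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash", "reference_config_toml"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemConfig(_Strict):
    preset: Literal["binder", "rod"] = "binder"
    path: str | None = None          # overrides preset: load a saved system
    seed: int = 7


class RCConfig(_Strict):
    name: str
    group_a: str                     # named group in the system
    group_b: str
    weighting: Literal["geometric", "mass"] = "geometric"
    range: tuple[float, float]
    n_zones: int = 3
    window: tuple[float, float] | None = None   # seeding window


class ZoneConfig(_Strict):
    overlap_fraction: float = Field(0.5, gt=0, lt=1)
    bins_per_zone: int = Field(4, ge=2)


class ScheduleConfig(_Strict):
    n_iterations: int = 3
    n_runs_per_iteration: int = 12
    steps_per_run: int = 4000
    snapshot_interval_steps: int = 100
    transition_interval_steps: int = 500


class DynamicsConfig(_Strict):
    temperature: float = Field(300.0, gt=0)
    dt: float = Field(8.0, gt=0)
    friction: float = Field(1.0, gt=0)
    wall_k: float = Field(10.0, ge=0)


class AnalysisConfig(_Strict):
    density_spacing: float = Field(1.0, gt=0)
    orientation_spacing: float = Field(2.0, gt=0)
    rho0: float = Field(0.001, gt=0)
    level_multiplier: float = Field(0.5, gt=0)
    contact_cutoff: float = Field(4.0, gt=0)
    orientation_threshold: float = Field(0.5, ge=0, le=1)


class RunConfig(_Strict):
    system: SystemConfig = SystemConfig()
    rcs: list[RCConfig]
    zones: ZoneConfig = ZoneConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    dynamics: DynamicsConfig = DynamicsConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    output_dir: str = "vczone_out"
    root_seed: int = 1


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        missing = [" -> ".join(str(loc) for loc in e["loc"])
                   for e in err.errors()]
        raise ConfigError(
            f"invalid run config {path}: " + "; ".join(
                f"{m}: {e['msg']}" for m, e in zip(missing, err.errors()))
        ) from err


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def reference_config_toml() -> str:
    """A complete default config (the shipped demo binder campaign)."""
    return """\
# vczone run configuration (all defaults spelled out)
output_dir = "vczone_out"
root_seed = 1

[system]
preset = "binder"        # or "rod"; or path = "system.json"
seed = 7

[[rcs]]
name = "alpha"           # cleft opening
group_a = "alpha_A"
group_b = "alpha_B"
weighting = "mass"
range = [8.0, 10.0]
n_zones = 2
window = [8.3, 9.6]

[[rcs]]
name = "beta"            # pocket lining -> ligand head
group_a = "cleft"
group_b = "ligand_head"
weighting = "geometric"
range = [1.5, 13.5]
n_zones = 3
window = [9.5, 12.5]

[[rcs]]
name = "gamma"           # rim -> ligand tail
group_a = "rim"
group_b = "ligand_tail"
weighting = "geometric"
range = [1.5, 15.5]
n_zones = 3
window = [8.5, 12.5]

[zones]
overlap_fraction = 0.5
bins_per_zone = 4

[schedule]
n_iterations = 3
n_runs_per_iteration = 12
steps_per_run = 4000
snapshot_interval_steps = 100
transition_interval_steps = 500

[dynamics]
temperature = 300.0
dt = 8.0
friction = 1.0
wall_k = 10.0

[analysis]
density_spacing = 1.0
orientation_spacing = 2.0
rho0 = 0.001
level_multiplier = 0.5
contact_cutoff = 4.0
orientation_threshold = 0.5
"""
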