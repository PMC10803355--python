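"""Run configuration: one human-editable YAML file with full defaults.

Every tunable of the pipeline lives here — road geometry, kinematic
parameters, per-group DFFS distributions, the scenario grid, the Power-Model
exponent, seeds and output locations. A config round-trips losslessly
through YAML, and every run writes a manifest (config hash, master seed,
package version) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .drivers import DffsParams, default_dffs_params
from .microsim import CameraLayout, RoadSpec, SimParams
from .scenarios import GridConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "manifest"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class RunConfig:
    road: RoadSpec = field(default_factory=RoadSpec)
    sim: SimParams = field(default_factory=SimParams)
    dffs: dict[str, DffsParams] = field(default_factory=default_dffs_params)
    grid: GridConfig = field(default_factory=GridConfig)
    detection_range: float = 150.0
    p2p_compliance: str = "cap"
    power_exponent: float = 3.0
    rud_threshold: float = 90.0
    n_seeds: int = 30
    master_seed: int = 0
    parallelism: int = 1
    output_dir: str = "results"

    def layout(self, sec_type: str) -> CameraLayout:
        return CameraLayout.for_type(
            sec_type, self.road, self.detection_range, self.p2p_compliance
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {k: list(v) for k, v in self.grid.factors().items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        try:
            if "road" in d:
                kwargs["road"] = RoadSpec(**d.pop("road"))
            if "sim" in d:
                kwargs["sim"] = SimParams(**d.pop("sim"))
            if "dffs" in d:
                kwargs["dffs"] = {
                    g: DffsParams(**p) for g, p in d.pop("dffs").items()
                }
            if "grid" in d:
                kwargs["grid"] = GridConfig(**d.pop("grid"))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config section: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            return cls(**kwargs, **d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def manifest(config: RunConfig, overrides: dict | None = None) -> dict:
    from . import __version__

    return {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "n_seeds": config.n_seeds,
        "code_version": __version__,
        "overrides": overrides or {},
    }


def write_manifest(config: RunConfig, out_dir, overrides: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest(config, overrides), fh, indent=2, default=float)
    return path
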