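"""Run configuration: strict YAML loading with schema validation.

A run config names a stage and provides the stage's parameter block;
unknown keys and type mismatches are rejected by name, defaults are
filled in, and every run writes a resolved copy of its configuration
next to its outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "default_config", "STAGES"]

# schema: {stage: {key: default}}; nested dicts are sub-blocks.
_SCHEMAS: dict[str, dict] = {
    "simulate": {
        "membrane": {
            "epsilon": 1.0, "mu": 3.0, "zeta": 4.0, "theta0": 0.0,
            "r_min": 2.0 ** (1.0 / 6.0), "r_cut": 2.6,
        },
        "vesicle": {"n_beads": 1500, "radius": 0.0},  # 0: derive from n_beads
        "dumbbell": {"lobe_radius": 3.0, "placement": "perpendicular",
                     "tilt_deg_max": 5.0},
        "sim": {
            "dt": 0.01, "n_steps": 100000, "kBT": 0.23,
            "gamma_t": 1.0, "gamma_r": 1.0,
            "epsilon_ad": 5.0, "r_cut_ad": 1.5,
            "tau0": 1.0, "snapshot_stride": 1000,
        },
        "tension": {"target_sigma": 0.0, "solute_diameter": 0.5},
    },
    "analyze": {
        "contact_cutoff": 1.5, "mesh_points": 500, "band": 0.8,
        "debounce_frames": 5, "bin_window": 0.0,
    },
    "tension": {
        "n_min": 3, "n_max": 20, "kbt_temperature": 298.0,
        "fit_noise_floor": False, "radius": 0.0,
    },
    "theory": {
        "d_s": 0.98e-6, "rho_frac": 0.6666666666666666,
        "W": 0.76e-6, "sigma": 0.0, "kappa_kbt": 20.0,
        "eta_eff": 0.8, "alpha": 1.0,
    },
    "synth": {
        "kind": "contours",
        "contours": {"sigma": 1.0e-7, "kappa_kbt": 20.0, "R": 1.0e-5,
                     "n_frames": 2000, "noise_floor": 0.0},
        "pathway": {"template": "parallel_full"},
        "wraptime": {"W": 0.76e-6, "eta_eff": 0.8, "cv": 0.05,
                     "sigma_min": 2.0e-9, "sigma_max": 2.2e-8, "n_sigma": 8},
    },
}

STAGES = tuple(_SCHEMAS)


@dataclass
class RunConfig:
    """A validated, fully resolved run configuration."""

    stage: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {"stage": self.stage, "seed": self.seed,
                "out_dir": self.out_dir, "log_level": self.log_level,
                "params": copy.deepcopy(self.params)}


def _validate_block(given: dict, schema: dict, path: str) -> dict:
    if not isinstance(given, dict):
        raise ValueError(f"config block '{path}' must be a mapping")
    resolved = {}
    for key, value in given.items():
        if key not in schema:
            raise ValueError(f"unknown config key '{path}{key}'")
        default = schema[key]
        if isinstance(default, dict):
            resolved[key] = _validate_block(value, default, f"{path}{key}.")
        else:
            if default is not None and not isinstance(
                    value, (type(default), int) if isinstance(default, float)
                    else type(default)):
                raise ValueError(
                    f"config key '{path}{key}' expects "
                    f"{type(default).__name__}, got {type(value).__name__}")
            resolved[key] = float(value) if isinstance(default, float) else value
    for key, default in schema.items():
        if key not in resolved:
            resolved[key] = (copy.deepcopy(default) if not isinstance(default, dict)
                             else _validate_block({}, default, f"{path}{key}."))
    return resolved


def default_config(stage: str) -> RunConfig:
    """Fully resolved default configuration for a stage."""
    if stage not in _SCHEMAS:
        raise ValueError(f"unknown stage '{stage}'; available: {list(_SCHEMAS)}")
    return RunConfig(stage=stage,
                     params=_validate_block({}, _SCHEMAS[stage], ""))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys raise by name."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    raw = dict(raw)
    stage = raw.pop("stage", None)
    if stage is None:
        raise ValueError(f"{path}: missing required key 'stage'")
    if stage not in _SCHEMAS:
        raise ValueError(f"{path}: unknown stage '{stage}'")
    seed = raw.pop("seed", 0)
    if not isinstance(seed, int):
        raise ValueError(f"{path}: config key 'seed' expects int")
    out_dir = raw.pop("out_dir", ".")
    log_level = raw.pop("log_level", "INFO")
    params = raw.pop("params", {})
    if raw:
        raise ValueError(f"{path}: unknown config key '{next(iter(raw))}'")
    resolved = _validate_block(params, _SCHEMAS[stage], "")
    return RunConfig(stage=stage, params=resolved, seed=seed,
                     out_dir=str(out_dir), log_level=str(log_level))


def save_config(config: RunConfig, path) -> None:
    """Write a resolved config as YAML (round-trips through load_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
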