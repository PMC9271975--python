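"""Run configuration: YAML schema, validation, and seed fan-out.

A run configuration is a nested mapping with one block per module plus a
global seed and output directory.  Unknown keys are rejected so typos fail
loudly; every run writes back its fully resolved configuration next to its
artifacts, and artifacts carry a hash of that resolved configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .cohort import DEFAULT_SCHEDULE
from .fields import FormFunction, ImmuneParameters, RadialGrid
from .size_dynamics import (GrowthDivisionSpec, MitosisKernel, SizeGrid,
                            UniformKernel)

__all__ = ["RunConfig", "ConfigError", "DEFAULTS"]

SCHEMA_VERSION = 1

DEFAULTS: dict[str, Any] = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "output_dir": "tumoreq-out",
    "size_dynamics": {
        "kernel": "mitosis",          # mitosis | uniform
        "kernel_mode": "auto",        # auto | direct | gaussian (mitosis)
        "kernel_width": None,         # Gaussian width; default one grid step
        "a": 0.103,                   # division rate (1/day), constant
        "V": 713.61,                  # growth rate (micron^3/day), constant
        "r_max": 6.0e4,               # size-axis truncation (micron^3)
        "n_cells": 300,
        "centered": True,
        "epsilon": 1.0e-6,            # inverse-power stopping threshold
        "shift": None,                # explicit shift overrides the bound
        "shift_safety": 1.05,
        "boundary": "ghost",          # ghost | dirichlet
        "max_iter": 20000,
    },
    "field": {
        "radius": 1.0,                # disk radius (mm)
        "n_cells": 100,
        "chi": 86.4,
        "D": 8.64e-5,
        "gamma": 2.0e-2,
        "K": 1.0e-2,
        "R_influx": 1.74e-7,
        "A": 2.0,                     # immune strength (delta amplitude)
        "theta": 0.1,                 # delta width (domain-radius units)
        "A_sigma": 5.0e-17,           # signal strength (sigma amplitude)
        "theta_sigma": 0.1,
    },
    "equilibrium": {
        "bracket": [1.0e-10, 10.0],
        "eps_d": 1.0e-8,
        "max_expand": 6,
    },
    "evolution": {
        "horizon": 3000.0,            # days
        "dt": 0.25,
        "cfl": 0.9,
        "record_every": 10,
        "initial_cells": 1.0,
        "drift_tol": 1.0e-5,
    },
    "sweep": {
        "vary": "a",
        "values": [0.072, 0.1, 0.15, 0.2, 0.3],
    },
    "sensitivity": {
        "degree": 5,
        "max_interaction": 2,
        "oversampling": 2.0,
        "n_mc": 100000,
        "radial_cells": 100,
    },
    "cohort": {
        "n_mice": 100,
        "schedule": {str(k): list(v) for k, v in DEFAULT_SCHEDULE.items()},
        "loq": {},
        "fit": False,
    },
}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _merge(defaults: Mapping, user: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], Mapping) and key not in (
                "schedule", "loq"):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


class RunConfig:
    """Validated, resolved run configuration with typed accessors."""

    def __init__(self, data: Mapping | None = None):
        self.data = _merge(DEFAULTS, dict(data or {}))
        for block in ("schedule", "loq"):   # YAML may parse keys as ints
            raw = self.data["cohort"][block] or {}
            self.data["cohort"][block] = {str(k): v for k, v in raw.items()}
        self._validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("top-level configuration must be a mapping")
        return cls(raw)

    def with_overrides(self, overrides: Mapping[str, Any]) -> "RunConfig":
        """Apply dotted-key overrides, e.g. {"field.gamma": 0.1}."""
        data = copy.deepcopy(self.data)
        for dotted, value in overrides.items():
            keys = dotted.split(".")
            node = data
            for k in keys[:-1]:
                if k not in node:
                    raise ConfigError(f"unknown configuration key: {dotted}")
                node = node[k]
            if keys[-1] not in node:
                raise ConfigError(f"unknown configuration key: {dotted}")
            node[keys[-1]] = value
        return RunConfig(data)

    def _validate(self) -> None:
        fld = self.data["field"]
        for key in ("chi", "D", "gamma", "K", "R_influx", "A", "theta",
                    "A_sigma", "theta_sigma", "radius"):
            if not fld[key] > 0:
                raise ConfigError(f"field.{key} must be positive")
        sd = self.data["size_dynamics"]
        if sd["kernel"] not in ("mitosis", "uniform"):
            raise ConfigError("size_dynamics.kernel must be mitosis|uniform")
        for key in ("a", "V", "r_max", "epsilon"):
            if not sd[key] > 0:
                raise ConfigError(f"size_dynamics.{key} must be positive")
        mu_a, mu_b = self.data["equilibrium"]["bracket"]
        if not 0 <= mu_a < mu_b:
            raise ConfigError("equilibrium.bracket must satisfy 0 <= a < b")

    # -- seed fan-out -----------------------------------------------------
    def child_seed(self, role: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        digest = hashlib.sha256(
            f"{int(self.data['seed'])}:{role}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2 ** 31)

    # -- typed accessors --------------------------------------------------
    def size_grid(self) -> SizeGrid:
        sd = self.data["size_dynamics"]
        return SizeGrid(float(sd["r_max"]), int(sd["n_cells"]),
                        centered=bool(sd["centered"]))

    def growth_division_spec(self) -> GrowthDivisionSpec:
        sd = self.data["size_dynamics"]
        if sd["kernel"] == "mitosis":
            kernel = MitosisKernel(mode=sd["kernel_mode"],
                                   width=sd["kernel_width"])
        else:
            kernel = UniformKernel()
        return GrowthDivisionSpec(float(sd["V"]), float(sd["a"]), kernel)

    def radial_grid(self) -> RadialGrid:
        fld = self.data["field"]
        return RadialGrid(float(fld["radius"]), int(fld["n_cells"]))

    def immune_parameters(self) -> ImmuneParameters:
        fld = self.data["field"]
        return ImmuneParameters(chi=float(fld["chi"]), D=float(fld["D"]),
                                gamma=float(fld["gamma"]), K=float(fld["K"]),
                                R_influx=float(fld["R_influx"]))

    def delta(self) -> FormFunction:
        fld = self.data["field"]
        return FormFunction(float(fld["A"]), float(fld["theta"]))

    def sigma(self) -> FormFunction:
        fld = self.data["field"]
        return FormFunction(float(fld["A_sigma"]), float(fld["theta_sigma"]))

    # -- provenance -------------------------------------------------------
    def resolved_yaml(self) -> str:
        return yaml.safe_dump(_jsonable(self.data), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]

    def dump(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "resolved-config.yaml"
        path.write_text(self.resolved_yaml())
        return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def metadata_block(config: RunConfig) -> dict:
    return {"config_hash": config.hash(),
            "schema_version": config.data["schema_version"],
            "seed": config.data["seed"]}


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(_jsonable(payload), f, indent=2)
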