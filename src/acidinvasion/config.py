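"""Run configuration: a flat YAML mapping with strict keys and full defaults.

An empty (or absent-key) configuration resolves to the published study
defaults: the Table of dimensionless groups (delta=12.5, rho_T=1,
Delta_T=4e-5, rho_L=70, kappa=10, c_S=1.5, zero inter-species
competition), steps at sigma=0.2/0.1 with omega=0.1, a 200-point unit
grid, and tolerances of 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import Grid1D
from .initial import InitialConditionSpec
from .params import DimensionlessParams
from .solver import SolverSettings


class ConfigError(ValueError):
    pass


def _bool(v):
    if isinstance(v, bool):
        return v
    raise TypeError


def _number(v):
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise TypeError
    return float(v)


def _str(v):
    if not isinstance(v, str):
        raise TypeError
    return v


def _number_list(v):
    if not isinstance(v, (list, tuple)):
        raise TypeError
    return tuple(_number(x) for x in v)


def _int(v):
    if isinstance(v, bool) or not isinstance(v, int):
        raise TypeError
    return int(v)


#: key -> (parser, default)
SCHEMA = {
    # dimensionless parameters
    "delta": (_number, 12.5),
    "rho_T": (_number, 1.0),
    "Delta_T": (_number, 4e-5),
    "rho_L": (_number, 70.0),
    "kappa": (_number, 10.0),
    "c_S": (_number, 1.5),
    "c_MA": (_number, 0.0),
    "c_AM": (_number, 0.0),
    # initial conditions
    "sigma_tissue": (_number, 0.2),
    "sigma_tumour": (_number, 0.1),
    "omega": (_number, 0.1),
    "include_TA": (_bool, True),
    "include_TM": (_bool, True),
    "step_convention": (_str, "plateau"),
    # grid
    "n_points": (_int, 200),
    "length": (_number, 1.0),
    # solver
    "rel_tol": (_number, 1e-10),
    "abs_tol": (_number, 1e-10),
    "stabilisation_rate": (_number, 100.0),
    "extinction_threshold": (_number, 1e-12),
    "snapshot_times": (_number_list, (0.0, 25.0, 50.0)),
    # experiment selection and experiment-specific keys
    "experiment": (_str, "simulate"),
    "t_end": (_number, 50.0),
    "which": (_str, "T_A"),
    "c_min": (_number, 0.0),
    "c_max": (_number, 2.0),
    "c_resolution": (_int, 20),
    "kappas": (_number_list, (5.0, 10.0, 20.0)),
    "amplitude": (_number, 1e-2),
    "mode": (_str, "multiplicative-noise"),
    "offset": (_number, 0.02),
    "seed": (_int, 0),
    "outdir": (_str, "runs"),
}

_PARAM_KEYS = ("delta", "rho_T", "Delta_T", "rho_L", "kappa", "c_S", "c_MA", "c_AM")
_ICS_KEYS = ("sigma_tissue", "sigma_tumour", "omega", "include_TA", "include_TM", "step_convention")
_SOLVER_KEYS = ("rel_tol", "abs_tol", "stabilisation_rate", "extinction_threshold", "snapshot_times")


@dataclass
class RunConfig:
    values: dict
    defaulted_keys: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.values[key]

    @property
    def params(self) -> DimensionlessParams:
        return DimensionlessParams(**{k: self.values[k] for k in _PARAM_KEYS})

    @property
    def ics(self) -> InitialConditionSpec:
        return InitialConditionSpec(**{k: self.values[k] for k in _ICS_KEYS})

    @property
    def grid(self) -> Grid1D:
        return Grid1D(n_points=self.values["n_points"], length=self.values["length"])

    @property
    def solver_settings(self) -> SolverSettings:
        return SolverSettings(**{k: self.values[k] for k in _SOLVER_KEYS})

    def as_manifest_dict(self) -> dict:
        out = {}
        for k, v in self.values.items():
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


def resolve_config(raw: dict | None) -> RunConfig:
    """Validate a flat mapping against the schema and fill in defaults."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a flat key-value mapping")
    values, defaulted = {}, []
    unknown = sorted(set(raw) - set(SCHEMA))
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    for key, (parse, default) in SCHEMA.items():
        if key in raw:
            try:
                values[key] = parse(raw[key])
            except TypeError:
                raise ConfigError(
                    f"configuration key {key!r} has wrong type: {type(raw[key]).__name__}"
                ) from None
        else:
            values[key] = default
            defaulted.append(key)
    cfg = RunConfig(values, defaulted)
    # construct eagerly so out-of-range values fail here, naming the stage
    try:
        cfg.params, cfg.ics, cfg.grid, cfg.solver_settings
    except ValueError as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML configuration file; None or an empty file mean defaults."""
    if path is None:
        return resolve_config({})
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return resolve_config(raw)
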