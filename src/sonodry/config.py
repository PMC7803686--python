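"""Default configuration and builders for material, air and scenario objects.

The defaults describe the study conditions: hot air at 65 degC, a ~12.5 mm
fresh radius, dry-mass fraction 0.138, and the published per-mode Arrhenius
diffusivities, transfer coefficients, acoustic powers and shrinkage slopes.
The GAB parameters are *synthetic* plausibility values for a dried berry at
65 degC (the study reports its isotherm fit only graphically); the noise
levels are likewise declared defaults, not measured ones.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from . import published
from .errors import DomainError
from .properties import AirState, GABParams, MaterialSpec
from .simulator import DryingScenario, NumericsConfig

__all__ = [
    "DEFAULT_CONFIG",
    "default_config",
    "load_config",
    "dump_config",
    "material_from_config",
    "air_from_config",
    "scenario_from_config",
    "numerics_from_config",
]

DEFAULT_CONFIG: dict = {
    "material": {
        "M0_kg": 3.5e-3,
        "f_dm": published.DRY_MASS_FRACTION,
        "r0_m": 0.0125,
        "T0_K": 298.15,
        # synthetic isotherm parameters (no published values exist)
        "gab": {"W_m": 0.10, "C": 10.0, "K": 0.85},
    },
    "air": {
        "T_air_K": 338.15,
        "RH_percent": 10.0,
        "rho_air": published.AIR_PROPERTIES["rho_air"],
        "Cp_air": published.AIR_PROPERTIES["Cp_air"],
        "alpha_air": published.AIR_PROPERTIES["alpha_air"],
        "D_air": published.AIR_PROPERTIES["D_air"],
    },
    "scenario": {
        "duration_s": 40000.0,
        # per-mode inputs; None means "use the published value"
        "h": None,
        "h_m": None,
        "P_US_W": None,
    },
    "numerics": {
        "n_nodes": 121,
        "rtol": 1e-6,
        "atol": 1e-8,
        "output_dt_s": 10.0,
        "early_dt_s": 0.5,
        "early_window_s": 60.0,
        "radius_update_every": 1,
    },
    "noise": {
        "kinetics_relative": 0.02,
        "cooling_K": 0.2,
        "calorimetry_K": 0.05,
        "sorption_relative": 0.03,
    },
    "sorption_aw_grid": [0.11, 0.22, 0.33, 0.43, 0.69, 0.75, 0.84],
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults merged with the YAML file at ``path`` (defaults if None)."""
    if path is None:
        return default_config()
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise DomainError(f"config file {path} must contain a mapping")
    return _merge(DEFAULT_CONFIG, user)


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)


def material_from_config(cfg: dict, mode: str = "none") -> MaterialSpec:
    """Material specification for one drying mode (shrinkage law and Arrhenius
    diffusivity are mode-specific measured inputs)."""
    m = cfg["material"]
    gab = m["gab"]
    return MaterialSpec(
        M0=m["M0_kg"],
        f_dm=m["f_dm"],
        r0=m["r0_m"],
        T0=m["T0_K"],
        gab=GABParams(W_m=gab["W_m"], C=gab["C"], K=gab["K"]),
        arrhenius=published.ARRHENIUS[mode],
        shrinkage=published.SHRINKAGE[mode],
    )


def air_from_config(cfg: dict) -> AirState:
    a = cfg["air"]
    return AirState(
        T_air=a["T_air_K"],
        RH=a["RH_percent"],
        rho_air=a["rho_air"],
        Cp_air=a["Cp_air"],
        alpha_air=a["alpha_air"],
        D_air=a["D_air"],
    )


def scenario_from_config(cfg: dict, mode: str) -> DryingScenario:
    s = cfg["scenario"]
    h, h_m = published.TRANSFER_COEFFICIENTS[mode]
    return DryingScenario(
        air=air_from_config(cfg),
        mode=mode,
        P_US=s["P_US_W"] if s.get("P_US_W") is not None else published.ULTRASOUND_POWER_W[mode],
        h=s["h"] if s.get("h") is not None else h,
        h_m=s["h_m"] if s.get("h_m") is not None else h_m,
        duration=s["duration_s"],
    )


def numerics_from_config(cfg: dict) -> NumericsConfig:
    n = cfg["numerics"]
    return NumericsConfig(
        n_nodes=n["n_nodes"],
        rtol=n["rtol"],
        atol=n["atol"],
        output_dt=n["output_dt_s"],
        early_dt=n["early_dt_s"],
        early_window=n["early_window_s"],
        radius_update_every=n["radius_update_every"],
    )
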