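"""Configuration schema and YAML round-tripping.

The config surface uses the anatomical/formulation literature units
(mm, µm, µL, µL/min, Pa, mOsM) with key names matching the parameter tables
(SA_exp, w_TF, bE, p0, Cs, ...); conversion to SI happens inside the
physics modules.  Configs are plain nested mappings: defaults are deep
copies of :data:`DEFAULT_CONFIG`, user files override leaves, and unknown
keys are rejected with their full key path.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .eye import DEFAULT_EYE_CONFIG

__all__ = ["DEFAULT_CONFIG", "load_config", "dump_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "geometry": {
        "SA_exp": 220.0,  # mm²
        "w_TF": 18.59,  # µm
        "L_lid": 57.0,  # mm
        "h_UF": 14.1,
        "h_UM": 0.934,
        "h_LM": 3.02,
        "h_LF": 10.2,
        "SA_UM": 0.0539,  # mm²
        "SA_LM": 0.242,
        "w_LA": 2.0,  # µm
        "w_BF": 7.0,
        "R_0": 0.25,  # mm
        "L_c": 0.012,  # m
    },
    "mesh": {
        "n_tearfilm_segments": 12,
        "n_canaliculus_nodes": 51,
        "n_sac_segments": 2,
    },
    "blink": {
        "t_interblink_phase": 5.5,  # s
        "t_closure": 0.04,
        "t_deposition": 0.18,
    },
    "physiology": {
        "Q_lacrimal": 1.0,  # µL/min
        "C_iso": 302.0,  # mOsM
        "V_max": 25.0,  # µL
    },
    "drainage": {
        "bE": 2.57,  # Pa·m
        "mu": 0.0015,  # Pa·s
        "n": 1.0,
        "K": 0.0015,  # Pa·sⁿ
        "p0": 400.0,  # Pa
        "psac": 0.0,
        # σ and R_m are calibrated (see docs/methods.md): tear surface
        # tension from the literature, meniscus curvature radii set once so
        # the steady radii and summed drainage land in physiological bands.
        "sigma": 0.0445,  # N/m
        "Rm_upper": 0.14e-3,  # m
        "Rm_lower": 0.15e-3,
        "feedback": True,  # scale R_m with meniscus volume in coupled runs
    },
    "evaporation": {
        "rate_uL_per_min": 0.2,
        "pressure_coeff": 0.1,  # K/Pa (calibration metadata)
        "pressure_temp_coeff": 3.0e4,  # K·m²·s/kg (calibration metadata)
        "active_phases": ["interblink"],
    },
    "drug": {
        "C_formulation": 1.0,  # mg/mL
        "Cs": 100.0,  # µg/mL
        "logP": 1.83,
        "M_drug": 0.035,  # mg
        "MW": 392.5,  # g/mol
        "rho": 1300.0,  # kg/m³
        "K_D": 2.5,
        "r_particle": 1.5,  # µm
        "diffusivity": None,  # m²/s; Stokes–Einstein from MW if null
        "particles_drain": True,
    },
    "dosing": [],  # list of {time_s, volume_uL, drug_mass_ug} or "formulation"
    "eye": copy.deepcopy(DEFAULT_EYE_CONFIG),
    "policy": {
        "name": "E",  # one of the STANDARD_POLICIES, or null with windows
        "windows": None,  # [[t0, t1, dt], ...] overriding the named policy
    },
    "simulation": {
        "n_cycles": 10,
        "record_every": 10,
        "pk_policy_windows": [[0.0, 5.5, 0.25], [5.5, 5.72, 0.02]],
    },
    "output": {"directory": "tearsim_out"},
    "seed": 0,  # fixtures only; the physics path is deterministic
}


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge ``override`` into a copy of ``base``; unknown keys error."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = merge_config(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults (or just the defaults)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise TypeError(f"config root must be a mapping, got {type(user)}")
    return merge_config(DEFAULT_CONFIG, user)


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
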