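"""Structured-text (TOML) run configuration.

A run file has up to six blocks — ``forcing``, ``metabolism``, ``oxygen``,
``iron``, ``cell_size``, ``temp_light`` — each holding scalar overrides of
the built-in defaults.  Unknown keys raise, so typos fail loudly.

Example::

    [forcing]
    photoperiod = [12, 12]
    irradiance = 150.0
    irradiance_shape = "square"
    o2_percent = 20.0
    temperature_C = 28.0
    salinity = 35.0

    [oxygen]
    membrane_factor = 6.45e4   # a value > 1 is read as a denominator

    [cell_size]
    r_low_um = 2.0
    r_high_um = 2.5
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .environment import CELSIUS_OFFSET, Forcing, o2_treatment_concentration
from .parameters import Parameters

__all__ = ["load_config", "forcing_from_dict", "parameters_from_dict"]

_OXYGEN_KEYS = {
    "membrane_factor": "diffusivity.membrane_factor",
    "D_ref": "diffusivity.D_ref",
    "R_max": "metabolism.R_max",
    "K_CS": "metabolism.K_CS",
}
_CELL_SIZE_KEYS = {
    "r_low_um": ("cell_size.r_low", 1e-6),
    "r_high_um": ("cell_size.r_high", 1e-6),
    "o2_low_uM": ("cell_size.o2_low", 1e-3),
    "o2_high_uM": ("cell_size.o2_high", 1e-3),
}


def forcing_from_dict(d: dict) -> Forcing:
    d = dict(d)
    light, dark = d.pop("photoperiod", (12.0, 12.0))
    temp = float(d.pop("temperature_C", 28.0)) + CELSIUS_OFFSET
    sal = float(d.pop("salinity", 35.0))
    if "o2_molar" in d and "o2_percent" in d:
        raise ValueError("give either o2_percent or o2_molar, not both")
    if "o2_molar" in d:
        o2 = float(d.pop("o2_molar"))
    else:
        o2 = o2_treatment_concentration(float(d.pop("o2_percent", 20.0)) / 100.0,
                                        temp, sal)
    f = Forcing(photoperiod_light_h=float(light), photoperiod_dark_h=float(dark),
                irradiance_peak=float(d.pop("irradiance", 150.0)),
                irradiance_shape=str(d.pop("irradiance_shape", "square")),
                ambient_o2=o2, temperature=temp, salinity=sal)
    if d:
        raise ValueError(f"unknown forcing keys: {sorted(d)}")
    return f


def parameters_from_dict(cfg: dict) -> Parameters:
    p = Parameters.default()
    overrides: dict[str, float] = {}
    for key, val in cfg.get("oxygen", {}).items():
        if key not in _OXYGEN_KEYS:
            raise ValueError(f"unknown oxygen key {key!r}")
        if key == "membrane_factor" and val > 1.0:
            val = 1.0 / val  # denominator convention
        overrides[_OXYGEN_KEYS[key]] = float(val)
    for key, val in cfg.get("cell_size", {}).items():
        if key == "fixed":
            p.cell_size.fixed = bool(val)
            continue
        if key not in _CELL_SIZE_KEYS:
            raise ValueError(f"unknown cell_size key {key!r}")
        target, scale = _CELL_SIZE_KEYS[key]
        overrides[target] = float(val) * scale
    for block in ("metabolism", "iron", "temp_light"):
        for key, val in cfg.get(block, {}).items():
            overrides[f"{block}.{key}"] = val
    if "fe_total" in cfg:
        p.fe_total = float(cfg["fe_total"])
    return p.with_overrides(**overrides) if overrides else p


def load_config(path: str | Path) -> tuple[Forcing, Parameters]:
    """Read a TOML run file into a (Forcing, Parameters) pair."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return forcing_from_dict(cfg.get("forcing", {})), parameters_from_dict(cfg)
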