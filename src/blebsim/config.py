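"""Configuration loading, validation and figure-protocol presets.

Configs are YAML with sections mirroring the physical components. Unknown
keys are rejected and every offending key is reported in one error. Presets
named after the figure protocols they reproduce ship with the package:
fig1_osmotic, fig2_single_bleb, fig3_oscillation, fig4_sweep,
fig5_asymmetry, fig6_hybrid.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import yaml

from . import fluid as fl
from . import kinetics as kin
from .errors import ConfigError
from .simulator import Cell, Protocol, build_cell

__all__ = ["load_config", "load_preset", "list_presets", "dump_config",
           "make_cell", "make_protocol", "SimConfig"]

_SECTIONS = {
    "fluid": {"eta_f", "eta_p_in", "eta_p_out", "lambda_p_in", "lambda_p_out",
              "L_p", "domain_size", "grid_shape", "dt", "momentum_rtol"},
    "cell": {"n_nodes", "radius", "newtonian"},
    "membrane": {"tension_stiffness", "bending_stiffness"},
    "cortex": {"kappa_c", "n_act_bar", "N_myo", "f_myo", "v_myo", "gamma0",
               "death_fraction"},
    "linkers": {"stiffness", "rest_length", "site_capacity"},
    "osmotic": {"Pi_in", "Pi_out", "permeability", "balance_offset",
                "vant_hoff"},
    "rates": {f.name for f in dataclasses.fields(kin.KineticRates)},
    "oscillation": {"period", "high_level", "low_level", "duty_fraction"},
    "protocol": {"kind", "duration", "detachment_arc", "linker_modulation",
                 "myosin_modulation", "osmotic_modulation_amplitude",
                 "ensemble_size", "seeds", "equilibration"},
}

_POSITIVE = {("fluid", "lambda_p_in"), ("fluid", "lambda_p_out"),
             ("fluid", "dt"), ("fluid", "domain_size"), ("cell", "radius"),
             ("rates", "K_tau"), ("protocol", "duration")}
_NON_NEGATIVE = {("fluid", "eta_f"), ("fluid", "eta_p_in"),
                 ("fluid", "eta_p_out"), ("membrane", "tension_stiffness"),
                 ("membrane", "bending_stiffness"), ("cortex", "kappa_c"),
                 ("cortex", "gamma0"), ("linkers", "stiffness"),
                 ("osmotic", "Pi_in"), ("osmotic", "Pi_out"),
                 ("osmotic", "permeability"),
                 ("rates", "k_adh_on"), ("rates", "k_off0"),
                 ("rates", "k_act_on"), ("rates", "k_act_off"),
                 ("rates", "k_myo_on"), ("rates", "k_myo_off")}


class SimConfig(dict):
    """Validated nested configuration (plain dict subclass)."""


def _validate(raw: dict) -> list[str]:
    problems = []
    if not isinstance(raw, dict):
        return ["top-level config must be a mapping"]
    for section in raw:
        if section not in _SECTIONS:
            problems.append(f"unknown section '{section}'")
            continue
        body = raw[section]
        if body is None:
            continue
        if not isinstance(body, dict):
            problems.append(f"section '{section}' must be a mapping")
            continue
        for key, val in body.items():
            if key not in _SECTIONS[section]:
                problems.append(f"unknown key '{section}.{key}'")
                continue
            if (section, key) in _POSITIVE and not (np.isscalar(val) and val > 0):
                problems.append(f"'{section}.{key}' must be > 0 (got {val!r})")
            if (section, key) in _NON_NEGATIVE and not (np.isscalar(val) and val >= 0):
                problems.append(f"'{section}.{key}' must be >= 0 (got {val!r})")
    L_p = (raw.get("fluid") or {}).get("L_p")
    if L_p is not None and L_p**2 <= 2:
        problems.append(f"'fluid.L_p' must satisfy L_p^2 > 2 (got {L_p!r})")
    dt = (raw.get("fluid") or {}).get("dt")
    rates = raw.get("rates") or {}
    if dt is not None:
        fastest = max([rates.get(k, 0.0) for k in
                       ("k_adh_on", "k_off0", "k_act_on", "k_myo_on")] + [0.0])
        if fastest * dt >= 0.1:
            problems.append(
                f"kinetic CFL violated: fastest rate x dt = {fastest * dt:.3g} >= 0.1")
    return problems


def load_config(path) -> SimConfig:
    """Load and validate a YAML config; raises ConfigError listing every
    offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = _validate(raw)
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return SimConfig(raw)


def dump_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def list_presets() -> list[str]:
    root = resources.files("blebsim") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> SimConfig:
    root = resources.files("blebsim") / "presets"
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise ConfigError(f"unknown preset '{name}'; available: {list_presets()}")
    raw = yaml.safe_load(path.read_text()) or {}
    problems = _validate(raw)
    if problems:
        raise ConfigError(f"preset '{name}' invalid:\n  " + "\n  ".join(problems))
    return SimConfig(raw)


def make_cell(cfg: SimConfig) -> Cell:
    """Build a Cell from a validated config."""
    fkw = dict(cfg.get("fluid") or {})
    if "grid_shape" in fkw:
        fkw["grid_shape"] = tuple(fkw["grid_shape"])
    params = fl.FluidParameters(**fkw)
    rates = kin.KineticRates(**(cfg.get("rates") or {}))
    cellsec = dict(cfg.get("cell") or {})
    okw = dict(cfg.get("osmotic") or {})
    vant_hoff = okw.pop("vant_hoff", False)
    cell = build_cell(
        n_nodes=cellsec.get("n_nodes", 128),
        radius=cellsec.get("radius", 10.0),
        fluid_params=params, rates=rates,
        newtonian=cellsec.get("newtonian", True),
        membrane_kw=cfg.get("membrane") or {},
        cortex_kw=cfg.get("cortex") or {},
        linker_kw=cfg.get("linkers") or {},
        osmo_kw=okw or None,
    )
    if vant_hoff:
        cell.osmo.osmolyte_amount = (cell.osmo.Pi_in
                                     * abs(cell.membrane.area()))
    return cell


def make_protocol(cfg: SimConfig) -> Protocol:
    psec = dict(cfg.get("protocol") or {})
    osc = cfg.get("oscillation")
    oscillation = kin.OscillationSignal(**osc) if osc else None
    if "detachment_arc" in psec:
        psec["detachment_arc"] = tuple(psec["detachment_arc"])
    if "seeds" in psec and psec["seeds"] is not None:
        psec["seeds"] = tuple(psec["seeds"])
    return Protocol(oscillation=oscillation, **psec)
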