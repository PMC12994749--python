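"""Canned experiments and parameter sweeps over the simulation protocols.

These wrap the figure presets with optional overrides at a configurable
resolution so the same experiment can run at production scale or at the
reduced problem sizes used for continuous testing (coarser grid, shorter
horizon, smaller ensembles). All randomness flows from explicit seeds.
"""

from __future__ import annotations

import numpy as np

from . import config as cfgmod
from . import simulator as sim
from . import tracks as tk
from .hybrid import AdhesionPolicy, run_hybrid_cycle

__all__ = ["apply_overrides", "single_bleb_experiment", "swim_ensemble_experiment",
           "hybrid_cycle_experiment", "coarse_overrides"]

#: reduced problem size for routine test runs: 64^2 grid, 48 membrane nodes
COARSE = {"fluid.grid_shape": [64, 64], "fluid.dt": 5.0e-4, "cell.n_nodes": 48}


def apply_overrides(cfg, overrides: dict | None):
    """Apply dotted-key overrides ('section.key': value) to a config copy."""
    import copy

    out = copy.deepcopy(dict(cfg))
    for dotted, value in (overrides or {}).items():
        section, key = dotted.split(".", 1)
        out.setdefault(section, {})
        if out[section] is None:
            out[section] = {}
        out[section][key] = value
    return cfgmod.SimConfig(out)


def coarse_overrides(extra: dict | None = None) -> dict:
    out = dict(COARSE)
    out.update(extra or {})
    return out


def single_bleb_experiment(overrides: dict | None = None,
                           preset: str = "fig2_single_bleb") -> dict:
    """One deterministic single-bleb cycle; returns net/peak displacement,
    peak bleb-front speed and phase markers."""
    cfg = apply_overrides(cfgmod.load_preset(preset), overrides)
    cell = cfgmod.make_cell(cfg)
    protocol = cfgmod.make_protocol(cfg)
    traj = sim.run_single_bleb(cell, protocol)
    disp = traj.displacement()
    return {
        "net_displacement": float(disp[-1]),
        "peak_displacement": float(disp.max()),
        "peak_front_speed": float(traj.diagnostics["peak_front_speed"]),
        "expansion_end": traj.diagnostics["expansion_end"],
        "cycle_time": float(traj.times[-1]),
        "max_bleb_area": float(traj.diagnostics["max_bleb_area"]),
        "completed": bool(traj.diagnostics["completed"]),
        "trajectory": traj,
    }


def swim_ensemble_experiment(oscillation: bool = True, n_cells: int = 5,
                             duration: float | None = None, seed: int = 0,
                             overrides: dict | None = None,
                             preset: str = "fig3_oscillation") -> dict:
    """Stochastic swimming ensemble; returns ensemble MSD, D_eff and bleb
    statistics. Without ``oscillation`` the contractility signal is held at
    its high level (sustained high cortical tension)."""
    cfg = apply_overrides(cfgmod.load_preset(preset), overrides)
    if not oscillation:
        osc = dict(cfg.get("oscillation") or {})
        if osc:
            osc["low_level"] = osc.get("high_level", 1.0)
            cfg["oscillation"] = osc
    if duration is not None:
        cfg["protocol"]["duration"] = duration
    cfg["protocol"]["ensemble_size"] = n_cells
    protocol = cfgmod.make_protocol(cfg)
    protocol.seeds = tuple(seed + 1000 * i for i in range(n_cells))
    trajs, failures = sim.run_stochastic_swim(lambda: cfgmod.make_cell(cfg),
                                              protocol)
    out = {"failures": failures, "trajectories": trajs}
    if trajs:
        ts = tk.TrackSet.from_arrays([t.times for t in trajs],
                                     [t.centroids for t in trajs])
        t0 = trajs[0].times
        dt_s = t0[1] - t0[0]
        lags = dt_s * np.arange(1, len(t0))
        _, ens = tk.msd(ts, lags)
        out["lags"] = lags
        out["ensemble_msd"] = ens
        window = min(16.0, lags[-1])
        try:
            out["D_eff"] = tk.fit_Deff(lags, ens, window=window)
        except ValueError:
            out["D_eff"] = None
        nus, pbs = [], []
        for tr in trajs:
            nu, pb = tk.bleb_stats(tr.bleb_log, tr.times[-1])
            nus.append(nu)
            if pb is not None:
                pbs.append(pb)
        out["nu_bleb"] = float(np.mean(nus))
        out["p_bleb"] = float(np.mean(pbs)) if pbs else None
    return out


def hybrid_cycle_experiment(placement: str = "front",
                            substrate_stiffness: float = 100.0,
                            overrides: dict | None = None, seed: int | None = None,
                            preset: str = "fig6_hybrid") -> dict:
    """One hybrid bleb + adhesion cycle; returns d_run, t_run and traction."""
    cfg = apply_overrides(cfgmod.load_preset(preset), overrides)
    cell = cfgmod.make_cell(cfg)
    protocol = cfgmod.make_protocol(cfg)
    policy = AdhesionPolicy(placement=placement,
                            substrate_stiffness=substrate_stiffness)
    rng = np.random.default_rng(seed) if seed is not None else None
    traj = run_hybrid_cycle(cell, protocol, policy, rng=rng)
    d = traj.diagnostics
    return {
        "d_run": d["d_run"], "t_run": d["t_run"],
        "D_cell": tk.motility_from_runs(d["d_run"], d["t_run"]),
        "peak_front_speed": d["peak_front_speed"],
        "completed": d["completed"],
        "traction": d["traction"],
        "trajectory": traj,
    }
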