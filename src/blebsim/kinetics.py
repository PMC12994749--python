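"""Stochastic kinetics of membrane-cortex linkers and cortex turnover.

Linkers associate in a force-independent manner and dissociate by force with
Bell's law, k_off = k_off0 * exp(F / F_b). Actin and myosin at attached
cortex nodes follow birth-death kinetics around a reference level; cortex
components at detached nodes decay first-order without reassembly; new cortex
is seeded under detached (bleb) membrane after a recruitment delay. All rates
are divided by the cortex turnover factor K_tau, so K_tau > 1 means slower
turnover. Updates use fixed-step tau-leaping (binomial removals, Poisson
additions) synchronized with the fluid step; passing ``rng=None`` selects the
mean-field (expected-value) limit used by the deterministic single-bleb
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import CortexState, LinkerEnsemble, MembraneState

__all__ = [
    "KineticRates",
    "OscillationSignal",
    "BlebEventLog",
    "linker_dissociation_rate",
    "sample_linker_kinetics",
    "update_cortex_turnover",
    "oscillation_value",
    "detect_bleb_nucleation",
    "wrapped_angle_difference_deg",
]


@dataclass
class KineticRates:
    """Kinetic rate constants; all [1/s] unless noted."""

    k_adh_on: float = 10.0       # linker association per free site
    k_off0: float = 1.0          # zero-force linker dissociation
    F_b: float = 2.0             # Bell force scale [pN]
    k_act_on: float = 1.0        # actin assembly (attached nodes)
    k_act_off: float = 1.0       # actin disassembly (attached nodes)
    k_act_decay: float = 8.0     # first-order disassembly of detached cortex
    k_myo_on: float = 1.0        # myosin recruitment (attached nodes)
    k_myo_off: float = 1.0       # myosin release
    K_tau: float = 1.0           # turnover factor: rates scale as 1/K_tau
    modulation_amplitude: float = 0.2   # spatial 1 + a*sin(theta) amplitude
    recruit_delay: float = 0.4   # delay before cortex reseeds under a bleb [s]
    seed_fraction: float = 0.15  # initial n_act of reseeded cortex / n_act_bar
    capture_radius: float = 0.6  # max membrane-cortex gap for rebinding [um]

    def __post_init__(self):
        for name in ("k_adh_on", "k_off0", "k_act_on", "k_act_off",
                     "k_act_decay", "k_myo_on", "k_myo_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K_tau <= 0:
            raise ValueError("K_tau must be positive")


@dataclass
class OscillationSignal:
    """Periodic square-wave cortical contractility multiplier S_osc(t)."""

    period: float = 10.0         # T_osc [s]
    high_level: float = 1.0
    low_level: float = 0.2
    duty_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.duty_fraction <= 1.0):
            raise ValueError("duty_fraction must lie in [0, 1]")
        if self.low_level > self.high_level:
            raise ValueError("low_level must not exceed high_level")


def oscillation_value(signal: OscillationSignal | None, t: float) -> float:
    """S_osc(t): high_level for the first duty_fraction of each period."""
    if signal is None:
        return 1.0
    phase = (t % signal.period) / signal.period
    return signal.high_level if phase < signal.duty_fraction else signal.low_level


@dataclass
class BlebEventLog:
    """Timestamped bleb nucleation events (time, polar angle, detachment arc)."""

    times: list = field(default_factory=list)        # [s]
    angles: list = field(default_factory=list)       # [rad]
    arc_lengths: list = field(default_factory=list)  # [um]
    _recent_nodes: list = field(default_factory=list)   # (t, frozenset of node idx)
    refractory: float = 0.5                          # [s]

    def append(self, t: float, angle: float, arc: float, nodes=frozenset()) -> None:
        if self.times and t <= self.times[-1]:
            t = np.nextafter(self.times[-1], np.inf)
        self.times.append(float(t))
        self.angles.append(float(angle))
        self.arc_lengths.append(float(arc))
        self._recent_nodes.append((float(t), frozenset(nodes)))

    def __len__(self) -> int:
        return len(self.times)

    def active_nodes(self, t: float) -> set:
        self._recent_nodes = [(t0, s) for t0, s in self._recent_nodes
                              if t - t0 <= self.refractory]
        out: set = set()
        for _, s in self._recent_nodes:
            out |= s
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times,
            "theta_deg": np.degrees(self.angles),
            "arc_um": self.arc_lengths,
        })


def linker_dissociation_rate(force, rates: KineticRates):
    """Bell's law: k_off = k_off0 * exp(F / F_b); compressed linkers use F=0."""
    f = np.maximum(np.asarray(force, dtype=float), 0.0)
    # cap the exponent: beyond ~e^50/s unbinding is instantaneous at any dt
    return rates.k_off0 * np.exp(np.minimum(f / rates.F_b, 50.0))


def sample_linker_kinetics(linkers: LinkerEnsemble, per_linker_force: np.ndarray,
                           rates: KineticRates, theta_c: np.ndarray,
                           rng: np.random.Generator | None, dt: float,
                           modulate: bool = False,
                           bind_allowed: np.ndarray | None = None) -> np.ndarray:
    """One tau-leap of linker association/dissociation; returns bound counts.

    Unbinding: binomial with per-linker probability 1 - exp(-k_off dt), k_off
    from Bell's law at the current per-linker tensile force. Binding: Poisson
    with mean k_on_eff * free_sites * dt, where k_on_eff includes the optional
    polar modulation 1 + a*sin(theta_c), clipped to the site capacity.
    ``bind_allowed`` masks nodes where no cortex is within reach. With
    ``rng=None`` the expected-value (mean-field) update is applied to
    fractional occupancies.
    """
    k_off = linker_dissociation_rate(per_linker_force, rates)
    k_on = rates.k_adh_on * np.ones_like(k_off)
    if modulate:
        k_on = rates.k_adh_on * (1.0 + rates.modulation_amplitude * np.sin(theta_c))
    if bind_allowed is not None:
        k_on = np.where(bind_allowed, k_on, 0.0)

    free = np.maximum(linkers.site_capacity - linkers.bound, 0.0)
    if rng is None:
        bound = linkers.bound + dt * (k_on * free - k_off * linkers.bound)
    else:
        p_off = -np.expm1(-k_off * dt)
        losses = rng.binomial(linkers.bound.astype(np.int64), p_off)
        gains = rng.poisson(k_on * free * dt)
        bound = linkers.bound - losses + gains
    linkers.bound = np.clip(bound, 0.0, linkers.site_capacity)
    return linkers.bound


def update_cortex_turnover(cortex: CortexState, membrane: MembraneState,
                           attached: np.ndarray, detach_time: np.ndarray,
                           rates: KineticRates, rng: np.random.Generator | None,
                           dt: float, t: float, signal: float = 1.0,
                           myosin_modulate: bool = False,
                           theta_c: np.ndarray | None = None) -> None:
    """One tau-leap of actin/myosin turnover, cortex death and reseeding.

    Attached alive nodes fluctuate around n_act_bar (birth rate
    k_act_on*n_act_bar/K_tau, per-unit death k_act_off/K_tau); myosin binds
    from the finite cell pool N_myo in proportion to local actin and is
    released first-order. Detached alive nodes decay first-order with no
    assembly. A node dies when its actin falls below death_fraction of
    n_act_bar; once the paired membrane node has been cortex-free for longer
    than recruit_delay, a fresh cortex node is seeded just beneath the
    membrane with seed_fraction * n_act_bar actin and no myosin.
    """
    inv = 1.0 / rates.K_tau
    alive = cortex.alive
    grow = alive & attached
    decay_only = alive & ~attached

    birth_act = np.where(grow, rates.k_act_on * cortex.n_act_bar * inv, 0.0)
    # detached cortex disassembles at its own (faster) first-order rate,
    # which sets the duration of the bleb expansion phase
    death_act = np.where(grow, rates.k_act_off * inv,
                         np.where(alive, rates.k_act_decay * inv, 0.0))

    n_nodes = cortex.n_nodes
    pool_free = max(cortex.N_myo - float(np.sum(cortex.n_myo)), 0.0)
    k_myo_on = rates.k_myo_on * np.ones(n_nodes)
    if myosin_modulate and theta_c is not None:
        k_myo_on = rates.k_myo_on * (1.0 + rates.modulation_amplitude * np.sin(theta_c))
    birth_myo = np.where(
        grow,
        k_myo_on * inv * (pool_free / n_nodes) * (cortex.n_act / cortex.n_act_bar),
        0.0,
    )
    death_myo = np.where(alive, rates.k_myo_off * inv, 0.0)

    if rng is None:
        cortex.n_act = np.maximum(
            cortex.n_act + dt * (birth_act - death_act * cortex.n_act), 0.0)
        cortex.n_myo = np.maximum(
            cortex.n_myo + dt * (birth_myo - death_myo * cortex.n_myo), 0.0)
    else:
        p_act = -np.expm1(-death_act * dt)
        p_myo = -np.expm1(-death_myo * dt)
        cortex.n_act = (cortex.n_act - rng.binomial(cortex.n_act.astype(np.int64), p_act)
                        + rng.poisson(birth_act * dt)).astype(float)
        cortex.n_myo = (cortex.n_myo - rng.binomial(cortex.n_myo.astype(np.int64), p_myo)
                        + rng.poisson(birth_myo * dt)).astype(float)
    cortex.n_act[~alive] = 0.0
    cortex.n_myo[~alive] = 0.0

    died = alive & (cortex.n_act < cortex.death_fraction * cortex.n_act_bar)
    if np.any(died):
        cortex.alive = cortex.alive & ~died
        cortex.n_act[died] = 0.0
        cortex.n_myo[died] = 0.0
        detach_time[died] = t

    # reseed cortex beneath bleb membrane after the recruitment delay
    ready = (~cortex.alive) & np.isfinite(detach_time) & (t - detach_time >= rates.recruit_delay)
    if np.any(ready):
        normals = membrane.outward_normals()
        cortex.positions[ready] = (membrane.positions[ready]
                                   - 0.05 * normals[ready])
        cortex.n_act[ready] = rates.seed_fraction * cortex.n_act_bar
        cortex.n_myo[ready] = 0.0
        cortex.velocities[ready] = 0.0
        cortex.alive[ready] = True
        detach_time[ready] = np.inf


def _detached_runs(detached: np.ndarray):
    """Maximal contiguous circular runs of True; list of index arrays."""
    n = len(detached)
    if detached.all():
        return [np.arange(n)]
    if not detached.any():
        return []
    # rotate so position 0 is attached, then find runs linearly
    start = int(np.argmin(detached))
    rolled = np.roll(detached, -start)
    runs = []
    idx = np.flatnonzero(rolled)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for chunk in np.split(idx, breaks + 1):
            runs.append((chunk + start) % n)
    return runs


def detect_bleb_nucleation(linkers: LinkerEnsemble, membrane: MembraneState,
                           log: BlebEventLog, t: float,
                           threshold_nodes: int = 3) -> bool:
    """Log a nucleation event for each fully detached membrane arc that first
    exceeds the threshold arc length and is disjoint from events still inside
    the refractory window. Event angle: centroid-relative polar angle of the
    arc midpoint. Returns True if any event was appended."""
    detached = linkers.bound <= 0.0
    runs = [r for r in _detached_runs(detached) if len(r) >= threshold_nodes]
    if not runs:
        return False
    active = log.active_nodes(t)
    theta = membrane.polar_angles()
    ds = membrane.segment_lengths()
    appended = False
    for run in runs:
        if active.intersection(run.tolist()):
            continue
        mid = run[len(run) // 2]
        arc = float(np.sum(ds[run]))
        log.append(t, float(theta[mid]), arc, nodes=frozenset(run.tolist()))
        appended = True
    return appended


def wrapped_angle_difference_deg(a_deg, b_deg):
    """Absolute angular separation wrapped to [0, 180] degrees."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)
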