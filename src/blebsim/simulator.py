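"""Simulation orchestration: single-bleb and stochastic-swim protocols.

Each time step is one operator-split cycle: (1) stochastic (or mean-field)
kinetics, (2) structural force evaluation, (3) immersed-boundary spreading,
(4) polymer stress, (5) periodic Stokes solve, (6) velocity interpolation and
structure advection, (7) FENE-P conformation update, (8) bleb-nucleation
detection. Global momentum conservation is enforced inside the Stokes solve:
the spread force density must integrate to zero (to tolerance) or the step
aborts — except for substrate-anchored adhesion forces, whose net reaction is
absorbed by the substrate and recorded as traction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fluid as fl
from . import kinetics as kin
from . import structures as st
from .errors import BlebsimError

__all__ = ["Protocol", "Trajectory", "Cell", "build_cell", "step",
           "run_single_bleb", "run_stochastic_swim", "equilibrate"]


@dataclass
class Protocol:
    """Which experiment to run and under what forcing."""

    kind: str = "stochastic_swim"            # single_bleb | stochastic_swim
    duration: float = 30.0                   # [s] after t = 0
    detachment_arc: tuple = (-18.0, 18.0)    # forced-detached arc [deg], single_bleb
    oscillation: kin.OscillationSignal | None = None
    linker_modulation: bool = False          # k_adh_on * (1 + a sin theta)
    myosin_modulation: bool = False          # k_myo_on * (1 + a sin theta)
    osmotic_modulation_amplitude: float = 0.0
    ensemble_size: int = 1
    seeds: tuple | None = None
    equilibration: float = 1.0               # [s] before t = 0

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass
class Trajectory:
    """Centroid time series and per-run diagnostics."""

    times: np.ndarray
    centroids: np.ndarray                    # (T, 2) [um]
    bleb_log: kin.BlebEventLog | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def displacement(self) -> np.ndarray:
        return np.linalg.norm(self.centroids - self.centroids[0], axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.times,
                             "x_um": self.centroids[:, 0],
                             "y_um": self.centroids[:, 1]})


@dataclass
class Cell:
    """Full simulation state of one cell plus bookkeeping."""

    fluid: fl.FluidState
    membrane: st.MembraneState
    cortex: st.CortexState
    linkers: st.LinkerEnsemble
    osmo: st.OsmoticModel
    rates: kin.KineticRates
    bleb_log: kin.BlebEventLog = field(default_factory=kin.BlebEventLog)
    time: float = 0.0
    newtonian: bool = True
    detach_time: np.ndarray = None           # cortex death time per node [s]
    no_rebind: np.ndarray = None             # protocol-forced rebinding lockout
    adhesions = None                         # AdhesionClutchSet (hybrid mode)
    traction: list = field(default_factory=list)   # (t, Fx, Fy) substrate sums
    material_update_every: int = 10
    conformation_every: int = 1
    cortex_substeps: int = 8
    spacing_check_every: int = 25
    bleb_threshold_nodes: int = 3
    detect_blebs: bool = True
    initial_center: np.ndarray = None
    initial_radius: float = None
    _n_steps: int = 0

    def __post_init__(self):
        n = self.membrane.n_nodes
        if self.detach_time is None:
            self.detach_time = np.full(n, np.inf)
        if self.no_rebind is None:
            self.no_rebind = np.zeros(n, dtype=bool)
        if self.initial_center is None:
            self.initial_center = self.membrane.centroid()
        if self.initial_radius is None:
            r = np.linalg.norm(self.membrane.positions - self.initial_center, axis=1)
            self.initial_radius = float(np.mean(r))

    @property
    def h(self) -> float:
        return self.fluid.params.h

    def radial_positions(self) -> np.ndarray:
        """Node distances from the *current* centroid [um]."""
        c = self.membrane.centroid()
        return np.linalg.norm(self.membrane.positions - c, axis=1)

    def bleb_area(self) -> float:
        """Membrane area protruding beyond the current effective radius.

        Measured about the current centroid against sqrt(area/pi), so a cell
        that has translated but regained a circular shape reads ~0 [um^2]."""
        r = self.radial_positions()
        r_eff = np.sqrt(abs(self.membrane.area()) / np.pi)
        ds = self.membrane.segment_lengths()
        return float(np.sum(np.maximum(r - r_eff, 0.0) * ds))


def build_cell(n_nodes: int = 128, radius: float = 10.0,
               fluid_params: fl.FluidParameters | None = None,
               rates: kin.KineticRates | None = None,
               newtonian: bool = True,
               membrane_kw: dict | None = None,
               cortex_kw: dict | None = None,
               linker_kw: dict | None = None,
               osmo_kw: dict | None = None) -> Cell:
    """Assemble an equilibrium-circle cell centred in the periodic box.

    The default intracellular osmotic pressure excess is set to the Laplace
    pressure of the default active cortical tension, Pi_in - Pi_out =
    f_myo * (N_myo / n_nodes) / radius, so the resting cell neither swells
    nor shrinks.
    """
    params = fluid_params or fl.FluidParameters()
    c = (params.domain_size / 2.0, params.domain_size / 2.0)
    membrane = st.MembraneState.circle(n_nodes, radius, c, **(membrane_kw or {}))
    cortex = st.CortexState.circle(
        n_nodes, radius - (linker_kw or {}).get("rest_length", 0.2), c,
        **(cortex_kw or {}))
    linkers = st.LinkerEnsemble.saturated(n_nodes, **(linker_kw or {}))
    okw = dict(osmo_kw or {})
    if "Pi_in" not in okw:
        # stationary per-node myosin is N_myo/(2 n) (pool-limited recruitment
        # balancing first-order release at equal rates)
        tension = cortex.f_myo * cortex.N_myo / (2.0 * n_nodes)
        okw.setdefault("Pi_out", 20.0)
        okw["Pi_in"] = okw["Pi_out"] + tension / radius
    osmo = st.OsmoticModel(**okw)

    state = fl.FluidState(params)
    if not newtonian:
        eta, lam = fl.assign_material_fields(membrane.positions, params)
        state.polymer_viscosity = eta
        state.relaxation_time = lam
    return Cell(fluid=state, membrane=membrane, cortex=cortex, linkers=linkers,
                osmo=osmo, rates=rates or kin.KineticRates(), newtonian=newtonian)


def _osmotic_zero_sum(f_osm: np.ndarray, membrane: st.MembraneState) -> np.ndarray:
    """Distribute any residual net osmotic force back over the membrane
    (arclength-weighted): the reaction to osmotic pumping is carried by the
    water, so the membrane-water pair is momentum-free."""
    net = f_osm.sum(axis=0)
    ds = membrane.segment_lengths()
    w = ds / ds.sum()
    return f_osm - w[:, None] * net[None, :]


def step(cell: Cell, protocol: Protocol, rng: np.random.Generator | None) -> Cell:
    """Advance one operator-split cycle of duration fluid.params.dt."""
    p = cell.fluid.params
    dt = p.dt
    t = cell.time
    s_osc = kin.oscillation_value(protocol.oscillation, t)
    theta = cell.membrane.polar_angles()

    # (1) kinetics: linkers, then cortex turnover / death / reseeding
    gap = np.linalg.norm(cell.cortex.positions - cell.membrane.positions, axis=1)
    bind_ok = (cell.cortex.alive & (gap <= cell.rates.capture_radius)
               & ~cell.no_rebind)
    per_linker = cell.linkers.per_linker_force(cell.membrane, cell.cortex)
    kin.sample_linker_kinetics(cell.linkers, per_linker, cell.rates, theta,
                               rng, dt, modulate=protocol.linker_modulation,
                               bind_allowed=bind_ok)
    attached = cell.linkers.bound >= 1.0
    alive_before = cell.cortex.alive.copy()
    kin.update_cortex_turnover(cell.cortex, cell.membrane, attached,
                               cell.detach_time, cell.rates, rng, dt, t,
                               signal=s_osc,
                               myosin_modulate=protocol.myosin_modulation,
                               theta_c=theta)
    reseeded = ~alive_before & cell.cortex.alive
    cell.no_rebind &= ~reseeded
    # linkers to cortex nodes that just died are torn off with the cortex;
    # otherwise their membrane-side force would be unpaired (momentum leak)
    cell.linkers.bound[~cell.cortex.alive] = 0.0

    # (2) structural forces
    if protocol.osmotic_modulation_amplitude:
        cell.osmo.Pi_in_modulation = (
            1.0 + protocol.osmotic_modulation_amplitude * np.sin(theta))
    mf = st.membrane_forces(cell.membrane, cell.linkers, cell.cortex, cell.osmo)
    f_membrane = mf.tension + mf.bending + mf.linker \
        + _osmotic_zero_sum(mf.osmotic, cell.membrane)

    v_f_cortex = st.interpolate_velocity(cell.fluid.velocity,
                                         cell.cortex.positions, cell.h)
    _, f_cortex = st.cortex_velocity_and_forces(
        cell.cortex, v_f_cortex, mf.linker_on_cortex, signal=s_osc)

    compensate = False
    f_adh = None
    if cell.adhesions is not None and cell.adhesions.any_bound():
        from .hybrid import adhesion_forces

        f_adh, reaction = adhesion_forces(cell.adhesions, cell.membrane)
        f_membrane = f_membrane + f_adh
        cell.traction.append((t, reaction[0], reaction[1]))
        compensate = True

    # (3) spread; (4)-(5) polymer stress + Stokes
    density = st.spread_forces(
        [(cell.membrane.positions, f_membrane),
         (cell.cortex.positions, f_cortex)], cell.h, p.grid_shape)
    sigma = None if cell.newtonian else fl.polymer_stress(cell.fluid)
    if compensate:
        v, pr, _ = fl.solve_stokes(density, sigma, p, compensate_net_force=True)
    else:
        v, pr = fl.solve_stokes(density, sigma, p)
    cell.fluid.velocity = v
    cell.fluid.pressure = pr

    # (6) advect membrane (no-slip + osmotic flux) and cortex (force balance)
    v_mem = st.interpolate_velocity(v, cell.membrane.positions, cell.h)
    st.advect_membrane(cell.membrane, v_mem, cell.osmo, dt)
    # the cortex balance is stiff when the porous drag is small (relaxation
    # time Gamma/k can approach dt), so its position update is sub-cycled
    # with frozen fluid velocity and membrane positions
    v_f_cortex = st.interpolate_velocity(v, cell.cortex.positions, cell.h)
    sub = dt / cell.cortex_substeps
    for _ in range(cell.cortex_substeps):
        f_link = st.linker_force_on_cortex(cell.membrane, cell.cortex,
                                           cell.linkers)
        v_c, _ = st.cortex_velocity_and_forces(
            cell.cortex, v_f_cortex, f_link, signal=s_osc)
        ok = cell.cortex.alive
        cell.cortex.positions[ok] += sub * v_c[ok]

    # (7) conformation kinetics and material-map refresh (viscoelastic only);
    # the conformation is advanced every `conformation_every` steps with the
    # accumulated dt (relaxation times are >> dt, semi-Lagrangian advection
    # is unconditionally stable)
    if not cell.newtonian:
        if cell._n_steps % cell.material_update_every == 0:
            eta, lam = fl.assign_material_fields(cell.membrane.positions, p)
            cell.fluid.polymer_viscosity = eta
            cell.fluid.relaxation_time = lam
        if (cell._n_steps + 1) % cell.conformation_every == 0:
            fl.evolve_conformation(cell.fluid, dt * cell.conformation_every)

    # (8) bleb nucleation events
    if cell.detect_blebs:
        kin.detect_bleb_nucleation(cell.linkers, cell.membrane, cell.bleb_log,
                                   t, threshold_nodes=cell.bleb_threshold_nodes)

    if cell.spacing_check_every and cell._n_steps % cell.spacing_check_every == 0:
        cell.membrane.check_spacing(cell.h)

    cell.time = t + dt
    cell._n_steps += 1
    return cell


def equilibrate(cell: Cell, protocol: Protocol, duration: float | None = None) -> Cell:
    """Relax the assembled cell with mean-field kinetics and no bleb logging,
    then reset the clock to t = 0."""
    dur = protocol.equilibration if duration is None else duration
    quiet = Protocol(kind=protocol.kind, duration=dur, oscillation=None)
    cell.detect_blebs = False
    n = int(round(dur / cell.fluid.params.dt))
    for _ in range(n):
        step(cell, quiet, None)
    cell.detect_blebs = True
    cell.time = 0.0
    cell._n_steps = 0
    cell.initial_center = cell.membrane.centroid()
    r = np.linalg.norm(cell.membrane.positions - cell.initial_center, axis=1)
    cell.initial_radius = float(np.mean(r))
    return cell


def force_detachment(cell: Cell, arc_deg: tuple) -> np.ndarray:
    """Break membrane-cortex linkers over a polar-angle arc (protocol t = 0).

    Rebinding at those nodes is locked out until their cortex has turned over
    and reseeded (mimicking local linker downregulation)."""
    theta = np.degrees(cell.membrane.polar_angles())
    lo, hi = arc_deg
    d = (theta - lo) % 360.0
    width = (hi - lo) % 360.0 or 360.0
    mask = d <= width
    cell.linkers.bound[mask] = 0.0
    cell.no_rebind |= mask
    return mask


class FrontTracker:
    """Smoothed bleb-front kinematics and end-of-expansion detection.

    Front speed is a backward difference over a ~20 ms window — long enough
    to filter the impulsive transient of the protocol's instantaneous linker
    release, short enough to resolve genuine expansion bursts. Expansion
    ends when the (window-smoothed) bleb area first falls a few percent
    below its running maximum, after the front has advanced a minimum
    distance — i.e. when the bleb demonstrably starts to retract."""

    def __init__(self, r0: float, dt: float, window: float = 0.02,
                 min_advance: float = 0.3, settle: float = 0.05,
                 area_drop: float = 0.97):
        self.r0 = r0
        self.dt = dt
        self.n_win = max(int(round(window / dt)), 1)
        self.min_advance = min_advance
        self.settle = settle
        self.area_drop = area_drop
        self.history = [r0]
        self._area_acc: list = []
        self._area_peak = 0.0
        self.peak_speed = 0.0
        self.expansion_end: float | None = None

    def update(self, r: float, area: float, t: float) -> None:
        self.history.append(r)
        self._area_acc.append(area)
        if len(self._area_acc) > self.n_win:
            self._area_acc.pop(0)
        if len(self.history) <= self.n_win or t < self.settle:
            return
        v = (self.history[-1] - self.history[-1 - self.n_win]) \
            / (self.n_win * self.dt)
        if self.expansion_end is None:
            self.peak_speed = max(self.peak_speed, v)
            smoothed = sum(self._area_acc) / len(self._area_acc)
            self._area_peak = max(self._area_peak, smoothed)
            if (r - self.r0 >= self.min_advance and self._area_peak > 0.0
                    and smoothed < self.area_drop * self._area_peak):
                self.expansion_end = t


def run_single_bleb(cell: Cell, protocol: Protocol, sample_every: int = 10,
                    rng: np.random.Generator | None = None) -> Trajectory:
    """Deterministic (mean-field) single-bleb cycle.

    Equilibrates, forces detachment over ``protocol.detachment_arc`` at
    t = 0, and runs until the bleb has retracted below 5% of its maximum
    area (or the duration cap, with a warning in the diagnostics). Records
    centroid, bleb area and bleb-front kinematics.
    """
    equilibrate(cell, protocol)
    arc_mask = force_detachment(cell, protocol.detachment_arc)
    front_idx = int(np.flatnonzero(arc_mask)[np.count_nonzero(arc_mask) // 2])

    dt = cell.fluid.params.dt
    n_steps = int(round(protocol.duration / dt))
    times, cents, areas, fronts = [], [], [], []
    tracker = FrontTracker(cell.radial_positions()[front_idx], dt)
    max_area = 0.0
    completed = False

    for i in range(n_steps):
        step(cell, protocol, rng)
        r = cell.radial_positions()[front_idx]
        a = cell.bleb_area()
        tracker.update(r, a, cell.time)
        max_area = max(max_area, a)
        if i % sample_every == 0 or i == n_steps - 1:
            times.append(cell.time)
            cents.append(cell.membrane.centroid())
            areas.append(a)
            fronts.append(r)
        if (max_area > 0.1 and a < 0.05 * max_area
                and tracker.expansion_end is not None):
            completed = True
    # the run continues to the duration cap even after the bleb-area marker:
    # net displacement is read after the post-retraction relaxation

    return Trajectory(
        times=np.asarray(times), centroids=np.asarray(cents),
        bleb_log=cell.bleb_log,
        diagnostics={
            "bleb_area": np.asarray(areas),
            "front_radius": np.asarray(fronts),
            "peak_front_speed": tracker.peak_speed,
            "expansion_end": tracker.expansion_end,
            "max_bleb_area": max_area,
            "completed": completed,
            "initial_radius": cell.initial_radius,
        })


def run_stochastic_swim(cell_factory, protocol: Protocol,
                        sample_every: int = 25):
    """Run an ensemble of stochastic swimming cells with distinct seeds.

    ``cell_factory()`` must return a freshly built Cell. Per-cell failures
    are recorded and the ensemble continues. Returns (trajectories,
    failures)."""
    seeds = protocol.seeds or tuple(range(protocol.ensemble_size))
    trajectories, failures = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        cell = cell_factory()
        try:
            equilibrate(cell, protocol)
            dt = cell.fluid.params.dt
            n_steps = int(round(protocol.duration / dt))
            times, cents = [0.0], [cell.membrane.centroid()]
            for i in range(n_steps):
                step(cell, protocol, rng)
                if (i + 1) % sample_every == 0 or i == n_steps - 1:
                    times.append(cell.time)
                    cents.append(cell.membrane.centroid())
            trajectories.append(Trajectory(
                times=np.asarray(times), centroids=np.asarray(cents),
                bleb_log=cell.bleb_log, seed=seed))
        except BlebsimError as exc:   # pragma: no cover - defensive
            failures.append((seed, repr(exc)))
    return trajectories, failures
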