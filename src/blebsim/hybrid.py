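"""Hybrid bleb + adhesion migration: bleb-driven front extension followed by
front focal-adhesion formation that rectifies retraction into net forward
translocation.

Adhesion clutches are Hookean springs in series with a compliant substrate
(effective stiffness k_eff = k_clutch*k_sub/(k_clutch+k_sub)), anchored at
the membrane positions reached at the end of bleb expansion. Their reaction
acts on the substrate, outside the fluid momentum budget — that broken
symmetry is exactly what distinguishes this mode from adhesion-free swimming.
Clutches unbind with exponential lifetimes (a few seconds); in the
deterministic mean-field protocol the bound fraction decays continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics as kin
from .simulator import Cell, Protocol, Trajectory, equilibrate, force_detachment, step
from .structures import MembraneState

__all__ = ["AdhesionClutchSet", "AdhesionPolicy", "form_adhesions",
           "adhesion_forces", "run_hybrid_cycle"]


@dataclass
class AdhesionPolicy:
    """Where and how densely clutches form when a bleb finishes expanding."""

    placement: str = "front"          # front | rear | uniform
    density: float = 3.0              # clutches per um of membrane arc
    clutch_stiffness: float = 100.0   # collective clutch spring [pN/um]
    substrate_stiffness: float = 1000.0  # k_sub [pN/um]
    mean_lifetime: float = 5.0        # [s]

    def __post_init__(self):
        if self.placement not in ("front", "rear", "uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.density < 0:
            raise ValueError("density must be non-negative")

    @property
    def k_eff(self) -> float:
        kc, ks = self.clutch_stiffness, self.substrate_stiffness
        if np.isinf(ks):
            return kc
        return kc * ks / (kc + ks)


@dataclass
class AdhesionClutchSet:
    """Active clutches: membrane node indices, anchors and occupancy.

    ``weight`` is 1/0 for stochastic bound/unbound clutches, or the
    continuous mean-field bound fraction exp(-(t - t_form)/tau)."""

    node_idx: np.ndarray
    anchors: np.ndarray               # (K, 2) [um]
    k_eff: float
    mean_lifetime: float
    formation_time: float
    weight: np.ndarray = None

    def __post_init__(self):
        if self.weight is None:
            self.weight = np.ones(len(self.node_idx))

    def any_bound(self) -> bool:
        return len(self.node_idx) > 0 and bool(np.any(self.weight > 1e-6))

    def update_occupancy(self, t: float, dt: float,
                         rng: np.random.Generator | None) -> None:
        if rng is None:
            frac = np.exp(-max(t - self.formation_time, 0.0)
                          / self.mean_lifetime)
            self.weight = np.full(len(self.node_idx), frac)
        else:
            p = -np.expm1(-dt / self.mean_lifetime)
            drop = rng.random(len(self.weight)) < p
            self.weight = np.where(drop, 0.0, self.weight)


def _policy_nodes(membrane: MembraneState, bleb_nodes: np.ndarray,
                  policy: AdhesionPolicy) -> np.ndarray:
    n = membrane.n_nodes
    if policy.placement == "uniform":
        return np.arange(n)
    if policy.placement == "front":
        return np.asarray(bleb_nodes)
    # rear: the contiguous arc diametrically opposite the bleb arc
    return (np.asarray(bleb_nodes) + n // 2) % n


def form_adhesions(membrane: MembraneState, bleb_nodes: np.ndarray,
                   policy: AdhesionPolicy, t: float) -> AdhesionClutchSet:
    """Anchor clutches at the current membrane positions over the policy
    region with zero initial extension; count = density x arc length."""
    region = _policy_nodes(membrane, bleb_nodes, policy)
    ds = membrane.segment_lengths()
    arc = float(np.sum(ds[region]))
    count = int(round(policy.density * arc))
    if count == 0 or len(region) == 0:
        return AdhesionClutchSet(np.empty(0, dtype=int), np.empty((0, 2)),
                                 policy.k_eff, policy.mean_lifetime, t)
    picks = region[np.linspace(0, len(region) - 1, count).round().astype(int)]
    anchors = membrane.positions[picks].copy()
    return AdhesionClutchSet(picks, anchors, policy.k_eff,
                             policy.mean_lifetime, t)


def adhesion_forces(clutches: AdhesionClutchSet, membrane: MembraneState):
    """Per-membrane-node clutch forces and the total reaction on the
    substrate. Bound clutch force = k_eff * (anchor - node position); the
    substrate reaction is equal and opposite (traction)."""
    f = np.zeros_like(membrane.positions)
    if len(clutches.node_idx):
        pull = clutches.k_eff * clutches.weight[:, None] * (
            clutches.anchors - membrane.positions[clutches.node_idx])
        np.add.at(f, clutches.node_idx, pull)
    return f, -f.sum(axis=0)


def run_hybrid_cycle(cell: Cell, protocol: Protocol, policy: AdhesionPolicy,
                     sample_every: int = 10,
                     rng: np.random.Generator | None = None) -> Trajectory:
    """One bleb cycle with front (or rear/uniform) adhesion formation.

    Runs the deterministic single-bleb machinery; when the bleb front's
    outward speed falls below 5% of its peak (end of expansion), clutches
    are anchored over the policy region. Reports net displacement d_run and
    cycle duration t_run."""
    equilibrate(cell, protocol)
    arc_mask = force_detachment(cell, protocol.detachment_arc)
    bleb_nodes = np.flatnonzero(arc_mask)
    front_idx = int(bleb_nodes[len(bleb_nodes) // 2])

    dt = cell.fluid.params.dt
    n_steps = int(round(protocol.duration / dt))
    times, cents, areas = [0.0], [cell.membrane.centroid()], [0.0]
    from .simulator import FrontTracker

    tracker = FrontTracker(cell.radial_positions()[front_idx], dt)
    max_area = 0.0
    completed = False
    t_cycle = None

    for i in range(n_steps):
        if cell.adhesions is not None:
            cell.adhesions.update_occupancy(cell.time, dt, rng)
        step(cell, protocol, rng)
        r = cell.radial_positions()[front_idx]
        a = cell.bleb_area()
        had_end = tracker.expansion_end is not None
        tracker.update(r, a, cell.time)
        if tracker.expansion_end is not None and not had_end:
            cell.adhesions = form_adhesions(cell.membrane, bleb_nodes, policy,
                                            cell.time)
        max_area = max(max_area, a)
        if (i + 1) % sample_every == 0 or i == n_steps - 1:
            times.append(cell.time)
            cents.append(cell.membrane.centroid())
            areas.append(a)
        if (not completed and max_area > 0.1 and a < 0.05 * max_area
                and tracker.expansion_end is not None):
            completed = True
            t_cycle = cell.time

    times = np.asarray(times)
    cents = np.asarray(cents)
    d_run = float(np.linalg.norm(cents[-1] - cents[0]))
    t_run = float(t_cycle if t_cycle is not None else times[-1])
    traction = np.asarray(cell.traction) if cell.traction else np.empty((0, 3))
    return Trajectory(
        times=times, centroids=cents, bleb_log=cell.bleb_log,
        diagnostics={
            "d_run": d_run, "t_run": t_run,
            "bleb_area": np.asarray(areas),
            "peak_front_speed": tracker.peak_speed,
            "expansion_end": tracker.expansion_end,
            "completed": completed,
            "traction": traction,
        })
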