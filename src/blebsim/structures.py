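"""Lagrangian membrane and poroelastic actomyosin cortex.

The plasma membrane is a closed elastic curve carrying tension, bending,
Hookean membrane-cortex linker, and osmotic forces. The cortex is a closed
chain of actomyosin nodes: elastic tension proportional to the local actin
amount (stiffness per actin unit kappa_c), active contractile tension from
myosin motors with a linear force-velocity relation, and a cytoplasmic drag
proportional to local actin (porous-network friction). The cortex is massless:
its nodal velocity follows from the instantaneous force balance

    Gamma(n_act) (v_c - v_f) = F_elastic + F_active + F_linker,

and by Newton's third law the force the cortex transmits to the fluid through
that drag is exactly the right-hand side, so that when membrane and cortex
forces are spread together the grid integral of the total force density
vanishes to round-off (global momentum conservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .errors import GeometryError, IllPosedBalanceError

__all__ = [
    "MembraneState",
    "CortexState",
    "LinkerEnsemble",
    "OsmoticModel",
    "MembraneForces",
    "membrane_forces",
    "cortex_velocity_and_forces",
    "spread_forces",
    "interpolate_velocity",
    "advect_membrane",
    "polygon_area",
    "polygon_centroid",
    "circle_nodes",
]


def polygon_area(positions: np.ndarray) -> float:
    """Signed shoelace area (positive for counterclockwise orientation)."""
    x, y = positions[:, 0], positions[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(positions: np.ndarray) -> np.ndarray:
    """Area centroid of the closed polygon."""
    x, y = positions[:, 0], positions[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def circle_nodes(n: int, radius: float, center) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def is_simple(positions: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    p = Polygon(positions)
    return p.is_valid and p.is_simple


@dataclass
class MembraneState:
    """Closed elastic membrane curve (counterclockwise node ordering)."""

    positions: np.ndarray                  # (N, 2) [um]
    rest_lengths: np.ndarray               # (N,) segment i connects node i, i+1
    tension_stiffness: float = 40.0        # [pN/um]
    bending_stiffness: float = 0.5         # [pN.um^2]

    @classmethod
    def circle(cls, n: int, radius: float, center=(0.0, 0.0), **kw) -> "MembraneState":
        pos = circle_nodes(n, radius, center)
        seg = np.roll(pos, -1, axis=0) - pos
        return cls(positions=pos, rest_lengths=np.linalg.norm(seg, axis=1), **kw)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def segment_vectors(self) -> np.ndarray:
        return np.roll(self.positions, -1, axis=0) - self.positions

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def normal_weights(self) -> np.ndarray:
        """Outward normal times arclength weight per node: 0.5*rot(x_{i+1}-x_{i-1}).

        The vectors sum to zero exactly over the closed curve, so any uniform
        pressure-like load is globally momentum-free by construction.
        """
        t = np.roll(self.positions, -1, axis=0) - np.roll(self.positions, 1, axis=0)
        return 0.5 * np.column_stack([t[:, 1], -t[:, 0]])

    def outward_normals(self) -> np.ndarray:
        nw = self.normal_weights()
        norm = np.linalg.norm(nw, axis=1, keepdims=True)
        return nw / np.maximum(norm, 1e-300)

    def polar_angles(self) -> np.ndarray:
        """Node polar angle theta_c about the area centroid, CCW from +x."""
        c = polygon_centroid(self.positions)
        d = self.positions - c
        return np.arctan2(d[:, 1], d[:, 0])

    def area(self) -> float:
        return polygon_area(self.positions)

    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.positions)

    def check_spacing(self, h: float) -> None:
        L = self.segment_lengths()
        if L.min() < 0.5 * h or L.max() > 2.0 * h:
            raise GeometryError(
                f"membrane node spacing [{L.min():.3g}, {L.max():.3g}] um left "
                f"the IBM accuracy window [{0.5*h:.3g}, {2*h:.3g}] um"
            )


@dataclass
class CortexState:
    """Closed actomyosin cortex chain paired one-to-one with membrane nodes."""

    positions: np.ndarray                  # (N, 2) [um]
    rest_lengths: np.ndarray               # (N,)
    n_act: np.ndarray                      # actin units per node
    n_myo: np.ndarray                      # myosin motors per node
    alive: np.ndarray                      # bool per node
    kappa_c: float = 0.1                   # cortical stiffness per actin unit [pN/um]
    n_act_bar: float = 2.0e4               # reference actin per node
    N_myo: float = 12800.0                 # total myosin pool in the cell
    f_myo: float = 4.0e-2                  # stall force per motor [pN]
    v_myo: float = 0.5                     # unloaded shortening speed [um/s]
    gamma0: float = 0.01                   # drag per actin unit [pN.s/um]
    death_fraction: float = 0.01           # node dies below this x n_act_bar
    velocities: np.ndarray = None          # previous step velocities [um/s]

    @classmethod
    def circle(cls, n: int, radius: float, center=(0.0, 0.0), **kw) -> "CortexState":
        pos = circle_nodes(n, radius, center)
        seg = np.roll(pos, -1, axis=0) - pos
        defaults = dict(
            positions=pos,
            rest_lengths=np.linalg.norm(seg, axis=1),
            alive=np.ones(n, dtype=bool),
        )
        defaults.update(kw)
        if "n_act" not in kw:
            defaults["n_act"] = np.full(n, defaults.get("n_act_bar", 2.0e4))
        if "n_myo" not in kw:
            # pool-limited stationary occupancy: N_myo / (2 n)
            defaults["n_myo"] = np.full(n, defaults.get("N_myo", 12800.0) / (2 * n))
        return cls(**defaults)

    def __post_init__(self):
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def drag_coefficients(self) -> np.ndarray:
        return self.gamma0 * self.n_act


@dataclass
class LinkerEnsemble:
    """Hookean membrane-cortex linkers, node i of the membrane to node i of
    the cortex. ``bound`` holds bound-linker counts (float so the mean-field
    limit can use fractional occupancy)."""

    bound: np.ndarray                      # (N,)
    stiffness: float = 2.0                 # per linker [pN/um]
    rest_length: float = 0.2               # [um]
    site_capacity: float = 20.0            # max linkers per node

    @classmethod
    def saturated(cls, n: int, **kw) -> "LinkerEnsemble":
        obj = cls(bound=np.zeros(n), **kw)
        obj.bound[:] = obj.site_capacity
        return obj

    def extensions(self, membrane: MembraneState, cortex: CortexState) -> np.ndarray:
        d = cortex.positions - membrane.positions
        return np.linalg.norm(d, axis=1) - self.rest_length

    def per_linker_force(self, membrane: MembraneState, cortex: CortexState) -> np.ndarray:
        """Tensile force carried by each bound linker [pN]; compressed -> 0."""
        return self.stiffness * np.maximum(self.extensions(membrane, cortex), 0.0)


@dataclass
class OsmoticModel:
    """Osmotic pressures across the membrane.

    Pi_in is either fixed or, when ``osmolyte_amount`` is set, van 't Hoff:
    Pi_in = osmolyte_amount / enclosed_area (2D convention). A nonzero
    ``permeability`` adds a water-flux normal slip to membrane advection,
    driven by (Pi_in - Pi_out - balance_offset); ``balance_offset`` is the
    mechanical pressure jump at osmotic equilibrium (cortical + membrane
    Laplace pressure), so the balanced preset neither swells nor shrinks.
    """

    Pi_in: float = 60.0                    # [pN/um^2]
    Pi_out: float = 20.0                   # [pN/um^2]
    osmolyte_amount: float | None = None   # [pN] (pressure x area), optional
    permeability: float = 0.0              # [um/(s.pN/um^2)]
    balance_offset: float = 0.0            # [pN/um^2]
    Pi_in_modulation: np.ndarray | None = None   # per-node multiplier, optional

    def __post_init__(self):
        if self.Pi_in < 0 or self.Pi_out < 0:
            raise ValueError("osmotic pressures must be non-negative")

    def intracellular_pressure(self, area: float) -> float:
        if self.osmolyte_amount is not None:
            return self.osmolyte_amount / area
        return self.Pi_in

    def pressure_jump(self, membrane: MembraneState) -> np.ndarray:
        """Per-node Pi_in - Pi_out, including optional spatial modulation."""
        pin = self.intracellular_pressure(abs(membrane.area()))
        pin = pin * (self.Pi_in_modulation if self.Pi_in_modulation is not None else 1.0)
        return pin - self.Pi_out


@dataclass
class MembraneForces:
    tension: np.ndarray
    bending: np.ndarray
    linker: np.ndarray        # force on membrane nodes from linkers
    osmotic: np.ndarray
    linker_on_cortex: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.tension + self.bending + self.linker + self.osmotic


def _segment_tension_forces(positions: np.ndarray, tension: np.ndarray,
                            mask: np.ndarray | None = None) -> np.ndarray:
    """Nodal forces from per-segment tensions T_i on segment (i, i+1).

    Positive tension pulls the two endpoints together; internal by
    construction (equal and opposite at the endpoints).
    """
    from ._kernels_numba import segment_tension_core

    n = len(positions)
    m = np.ones(n, dtype=np.bool_) if mask is None else np.asarray(mask, dtype=np.bool_)
    out = np.zeros((n, 2))
    ok = segment_tension_core(np.ascontiguousarray(positions, dtype=np.float64),
                              np.ascontiguousarray(tension, dtype=np.float64),
                              m, out)
    if ok < 0:
        raise GeometryError("degenerate zero-length segment")
    return out


def linker_force_on_cortex(membrane: MembraneState, cortex: CortexState,
                           linkers: LinkerEnsemble) -> np.ndarray:
    """Hookean linker force on each cortex node [pN] (tensile only)."""
    from ._kernels_numba import linker_core

    f_mem = np.zeros_like(membrane.positions)
    f_cor = np.zeros_like(membrane.positions)
    linker_core(np.ascontiguousarray(membrane.positions),
                np.ascontiguousarray(cortex.positions),
                np.ascontiguousarray(linkers.bound, dtype=np.float64),
                float(linkers.stiffness), float(linkers.rest_length),
                f_mem, f_cor)
    return f_cor


def membrane_forces(membrane: MembraneState, linkers: LinkerEnsemble | None,
                    cortex: CortexState | None, osmo: OsmoticModel) -> MembraneForces:
    """All nodal forces on the membrane [pN].

    Tension: Hookean springs along segments from rest lengths. Bending:
    gradient of a quadratic second-difference (discrete curvature) energy.
    Linkers: Hookean toward the paired cortex node, tensile only. Osmotic:
    (Pi_in - Pi_out) along the outward normal with arclength weight. All
    internal pairs (tension, bending, linker) sum to zero exactly; the
    osmotic sum vanishes for uniform pressure jump because the normal
    weights close around the curve.
    """
    x = membrane.positions
    n = membrane.n_nodes

    L = membrane.segment_lengths()
    T = membrane.tension_stiffness * (L - membrane.rest_lengths)
    f_tension = _segment_tension_forces(x, T)

    ds = float(np.mean(membrane.rest_lengths))
    d2 = np.roll(x, -1, axis=0) - 2.0 * x + np.roll(x, 1, axis=0)
    f_bending = -(membrane.bending_stiffness / ds**3) * (
        np.roll(d2, -1, axis=0) - 2.0 * d2 + np.roll(d2, 1, axis=0)
    )

    f_linker = np.zeros_like(x)
    f_linker_cortex = np.zeros_like(x)
    if linkers is not None and cortex is not None:
        from ._kernels_numba import linker_core

        linker_core(np.ascontiguousarray(x), np.ascontiguousarray(cortex.positions),
                    np.ascontiguousarray(linkers.bound, dtype=np.float64),
                    float(linkers.stiffness), float(linkers.rest_length),
                    f_linker, f_linker_cortex)

    dpi = osmo.pressure_jump(membrane)
    f_osmotic = np.atleast_1d(dpi)[:, None] * membrane.normal_weights()

    return MembraneForces(tension=f_tension, bending=f_bending, linker=f_linker,
                          osmotic=f_osmotic, linker_on_cortex=f_linker_cortex)


def cortex_structural_forces(cortex: CortexState, signal: float = 1.0) -> np.ndarray:
    """Elastic + active nodal forces on the cortex chain [pN].

    Elastic segment tension kappa_c * n_act_seg * (L - L0). Active segment
    tension f_myo * n_myo_seg * signal * (1 - v_shortening / v_myo), clamped
    to [0, 1.5] x stall (linear force-velocity; the shortening rate is taken
    from the previous step's cortex velocities). Segments with a dead
    endpoint carry no force.
    """
    from ._kernels_numba import cortex_forces_core

    out = np.zeros_like(cortex.positions)
    cortex_forces_core(np.ascontiguousarray(cortex.positions),
                       np.ascontiguousarray(cortex.rest_lengths, dtype=np.float64),
                       np.ascontiguousarray(cortex.alive),
                       np.ascontiguousarray(cortex.n_act, dtype=np.float64),
                       np.ascontiguousarray(cortex.n_myo, dtype=np.float64),
                       np.ascontiguousarray(cortex.velocities),
                       float(cortex.kappa_c), float(cortex.f_myo),
                       float(cortex.v_myo), float(signal), out)
    return out


def cortex_velocity_and_forces(cortex: CortexState, fluid_velocity_at_cortex: np.ndarray,
                               linker_force_on_cortex: np.ndarray,
                               signal: float = 1.0):
    """Solve the massless cortex force balance.

    Returns (node velocities, force transmitted to the fluid). Dead nodes
    exert and receive nothing and keep zero velocity. The transmitted force
    equals Gamma (v_c - v_f) = F_elastic + F_active + F_linker, i.e. minus
    the drag force the cortex receives from the fluid (Newton's third law).
    """
    n = cortex.n_nodes
    v_c = np.array(fluid_velocity_at_cortex, dtype=float, copy=True)
    f_spread = np.zeros((n, 2))
    if not np.any(cortex.alive):
        cortex.velocities = np.zeros((n, 2))
        return np.zeros((n, 2)), f_spread

    F = cortex_structural_forces(cortex, signal) + linker_force_on_cortex
    F[~cortex.alive] = 0.0
    gamma = cortex.drag_coefficients()
    bad = cortex.alive & (gamma <= 0.0) & (np.linalg.norm(F, axis=1) > 1e-12)
    if np.any(bad):
        raise IllPosedBalanceError(
            f"zero drag with nonzero force at cortex nodes {np.where(bad)[0]}"
        )
    ok = cortex.alive & (gamma > 0.0)
    v_c[ok] += F[ok] / gamma[ok, None]
    v_c[~cortex.alive] = 0.0
    f_spread[ok] = F[ok]
    cortex.velocities = v_c.copy()
    return v_c, f_spread


def spread_forces(node_sets, h: float, grid_shape) -> np.ndarray:
    """Spread one or more (positions, forces) pairs to a grid force density.

    Nodes outside the box wrap periodically. The grid integral equals the
    total nodal force to round-off (kernel partition of unity).
    """
    density = np.zeros((2,) + tuple(grid_shape))
    for positions, forces in node_sets:
        if len(positions):
            density += kernels.spread(positions, forces, h, grid_shape)
    return density


def interpolate_velocity(velocity: np.ndarray, positions: np.ndarray, h: float) -> np.ndarray:
    """Interpolate the grid velocity to node positions (adjoint kernel)."""
    return kernels.interpolate(velocity, positions, h)


def advect_membrane(membrane: MembraneState, nodal_velocities: np.ndarray,
                    osmo: OsmoticModel, dt: float, max_halvings: int = 3) -> np.ndarray:
    """Advance membrane positions by no-slip advection plus osmotic water flux.

    x <- x + dt [v + permeability (Pi_in - Pi_out - balance_offset) n_hat].
    With zero permeability and a divergence-free flow the enclosed area is
    conserved to discretization error. A post-step self-intersection rejects
    the step and retries with halved substeps (bounded)."""
    def slip(m: MembraneState) -> np.ndarray:
        if osmo.permeability == 0.0:
            return 0.0
        dpi = osmo.pressure_jump(m) - osmo.balance_offset
        return osmo.permeability * np.atleast_1d(dpi)[:, None] * m.outward_normals()

    for level in range(max_halvings + 1):
        nsub = 2**level
        sub = dt / nsub
        pos = membrane.positions.copy()
        ok = True
        trial = MembraneState(pos, membrane.rest_lengths,
                              membrane.tension_stiffness, membrane.bending_stiffness)
        for _ in range(nsub):
            trial.positions = trial.positions + sub * (nodal_velocities + slip(trial))
            if not is_simple(trial.positions):
                ok = False
                break
        if ok:
            membrane.positions = trial.positions
            return membrane.positions
    raise GeometryError("membrane self-intersects even after substep halving")
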