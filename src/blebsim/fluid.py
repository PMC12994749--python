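"""Incompressible inertialess viscoelastic fluid on a periodic 2D grid.

Momentum balance (depth-integrated 2D, Stokes limit):

    eta_f lap(v) - grad(p) + div(sigma_p) + F = 0,     div(v) = 0,

with the FENE-P polymer stress

    sigma_p = (eta_p / lambda_p) [ kappa_p / (1 - tr(kappa_p)/L_p^2) - I ]

and conformation-tensor kinetics

    d kappa/dt = (1/lambda_p)[I - kappa/(1 - tr kappa/L_p^2)]
                 - v.grad(kappa) + grad(v)^T.kappa + kappa.grad(v).

The Stokes problem is solved spectrally (FFT projection) on a periodic square
box; the pressure nullspace is fixed by the zero-mean convention and the
zero wavenumber of the velocity is pinned to zero, which is only consistent
when the net body force vanishes — the momentum-conservation precondition is
therefore checked explicitly and violated inputs raise instead of being
silently projected out.

Units: lengths um, time s, force pN. Viscosities are depth-integrated 2D
values: eta_f in pN.s/um^2, eta_p in pN.s/um; pressure in pN/um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConstitutiveError, GeometryError, MomentumViolationError

__all__ = [
    "FluidParameters",
    "FluidState",
    "assign_material_fields",
    "polymer_stress",
    "evolve_conformation",
    "solve_stokes",
    "velocity_gradient",
    "divergence",
    "fene_equilibrium",
]

# SPD safeguard constants: eigenvalue floor and FENE trace ceiling fraction.
_EIG_FLOOR = 1e-8
_FENE_CEIL = 1.0 - 1e-6


@dataclass
class FluidParameters:
    """Physical and numerical parameters of the viscoelastic fluid problem."""

    eta_f: float = 1.0            # fluid viscosity [pN.s/um^2]
    eta_p_in: float = 1.0         # intracellular polymer viscosity [pN.s/um]
    eta_p_out: float = 1.0        # extracellular polymer viscosity [pN.s/um]
    lambda_p_in: float = 100.0    # intracellular relaxation time [s]
    lambda_p_out: float = 10.0    # extracellular relaxation time [s]
    L_p: float = 10.0             # FENE extensibility (dimensionless)
    domain_size: float = 80.0     # periodic box edge [um]
    grid_shape: tuple[int, int] = (128, 128)
    dt: float = 1e-3              # [s]
    momentum_rtol: float = 1e-8   # net-force tolerance relative to sum |F|

    def __post_init__(self):
        if self.eta_f < 0 or self.eta_p_in < 0 or self.eta_p_out < 0:
            raise ValueError("viscosities must be non-negative")
        if self.lambda_p_in <= 0 or self.lambda_p_out <= 0:
            raise ValueError("relaxation times must be positive")
        if self.L_p**2 <= 2.0:
            raise ValueError("L_p^2 must exceed 2 for a 2D FENE-P equilibrium")

    @property
    def h(self) -> float:
        return self.domain_size / self.grid_shape[0]

    def wavenumbers(self):
        nx, ny = self.grid_shape
        kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=self.domain_size / nx)
        ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=self.domain_size / ny)
        return np.meshgrid(kx, ky, indexing="ij")

    def node_coords(self):
        nx, ny = self.grid_shape
        x = np.arange(nx) * (self.domain_size / nx)
        y = np.arange(ny) * (self.domain_size / ny)
        return np.meshgrid(x, y, indexing="ij")


@dataclass
class FluidState:
    """Eulerian fields: velocity, pressure, conformation and material maps."""

    params: FluidParameters
    velocity: np.ndarray = None        # (2, Nx, Ny) [um/s]
    pressure: np.ndarray = None        # (Nx, Ny) [pN/um^2]
    conformation: np.ndarray = None    # (3, Nx, Ny): kxx, kyy, kxy (symmetric)
    polymer_viscosity: np.ndarray = None   # (Nx, Ny) eta_p(x) [pN.s/um]
    relaxation_time: np.ndarray = None     # (Nx, Ny) lambda_p(x) [s]
    clamp_count: int = 0               # cumulative SPD/FENE safeguard events

    def __post_init__(self):
        shape = tuple(self.params.grid_shape)
        if self.velocity is None:
            self.velocity = np.zeros((2,) + shape)
        if self.pressure is None:
            self.pressure = np.zeros(shape)
        if self.conformation is None:
            keq = fene_equilibrium(self.params.L_p)
            self.conformation = np.zeros((3,) + shape)
            self.conformation[0] = keq
            self.conformation[1] = keq
        if self.polymer_viscosity is None:
            self.polymer_viscosity = np.full(shape, self.params.eta_p_out)
        if self.relaxation_time is None:
            self.relaxation_time = np.full(shape, self.params.lambda_p_out)


def fene_equilibrium(L_p: float) -> float:
    """Isotropic 2D FENE-P equilibrium: kappa = a*I with a/(1-2a/L^2) = 1."""
    return L_p**2 / (L_p**2 + 2.0)


def _smooth_indicator(chi: np.ndarray, passes: int = 1) -> np.ndarray:
    """Separable [1/4, 1/2, 1/4] smoothing; one pass reaches +-1 cell per
    axis, keeping the transition band within 2 grid cells total.

    The stencil sums to one so the discrete integral of the indicator is
    preserved exactly.
    """
    out = chi.astype(float)
    for _ in range(passes):
        for axis in (0, 1):
            out = 0.5 * out + 0.25 * (np.roll(out, 1, axis) + np.roll(out, -1, axis))
    return out


def assign_material_fields(membrane_polygon: np.ndarray, params: FluidParameters,
                           smooth: bool = True):
    """Inside/outside assignment of polymer viscosity and relaxation time.

    Grid nodes inside the (simple, closed) membrane polygon carry the
    intracellular values; outside carry extracellular; a smoothed transition
    band of width <= 2 cells blends them, consistent with the force-spreading
    kernel width.
    """
    from shapely.geometry import Polygon

    poly = np.asarray(membrane_polygon, dtype=float)
    if poly.shape[0] < 3:
        raise GeometryError("membrane polygon needs at least 3 vertices")
    sh = Polygon(poly)
    if not sh.is_valid or not sh.is_simple:
        raise GeometryError("membrane polygon is self-intersecting")

    if params.eta_p_in == params.eta_p_out and params.lambda_p_in == params.lambda_p_out:
        shape = tuple(params.grid_shape)
        return (np.full(shape, params.eta_p_in), np.full(shape, params.lambda_p_in))

    from matplotlib.path import Path

    gx, gy = params.node_coords()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    chi = Path(poly).contains_points(pts).reshape(params.grid_shape)
    chi = _smooth_indicator(chi) if smooth else chi.astype(float)
    eta = params.eta_p_out + (params.eta_p_in - params.eta_p_out) * chi
    lam = params.lambda_p_out + (params.lambda_p_in - params.lambda_p_out) * chi
    return eta, lam


def _fene_factor(conformation: np.ndarray, L_p: float) -> np.ndarray:
    tr = conformation[0] + conformation[1]
    denom = 1.0 - tr / L_p**2
    if np.any(denom <= 0):
        raise ConstitutiveError("tr(kappa_p) >= L_p^2: FENE bound violated")
    return 1.0 / denom


def polymer_stress(state: FluidState) -> np.ndarray:
    """FENE-P stress sigma_p = (eta_p/lambda_p)[kappa/(1 - tr kappa/L^2) - I].

    Returned as (3, Nx, Ny): sxx, syy, sxy. Identically zero wherever
    eta_p = 0.
    """
    k = state.conformation
    fac = _fene_factor(k, state.params.L_p)
    coef = state.polymer_viscosity / state.relaxation_time
    s = np.empty_like(k)
    s[0] = coef * (k[0] * fac - 1.0)
    s[1] = coef * (k[1] * fac - 1.0)
    s[2] = coef * (k[2] * fac)
    return s


def stress_divergence(sigma: np.ndarray, params: FluidParameters) -> np.ndarray:
    """Spectral divergence of a symmetric tensor field (3, Nx, Ny) -> (2, Nx, Ny)."""
    kx, ky = params.wavenumbers()
    sxx = np.fft.fft2(sigma[0])
    syy = np.fft.fft2(sigma[1])
    sxy = np.fft.fft2(sigma[2])
    fx = 1j * kx * sxx + 1j * ky * sxy
    fy = 1j * kx * sxy + 1j * ky * syy
    return np.real(np.stack([np.fft.ifft2(fx), np.fft.ifft2(fy)]))


def velocity_gradient(velocity: np.ndarray, params: FluidParameters) -> np.ndarray:
    """Spectral gradient G[i, j] = d v_i / d x_j, shape (2, 2, Nx, Ny)."""
    kx, ky = params.wavenumbers()
    out = np.empty((2, 2) + velocity.shape[1:])
    for i in range(2):
        vh = np.fft.fft2(velocity[i])
        out[i, 0] = np.real(np.fft.ifft2(1j * kx * vh))
        out[i, 1] = np.real(np.fft.ifft2(1j * ky * vh))
    return out


def divergence(velocity: np.ndarray, params: FluidParameters) -> np.ndarray:
    g = velocity_gradient(velocity, params)
    return g[0, 0] + g[1, 1]


def solve_stokes(force_density: np.ndarray, sigma_p: np.ndarray | None,
                 params: FluidParameters, compensate_net_force: bool = False):
    """Solve eta_f lap(v) - grad(p) + div(sigma_p) + F = 0 with div(v) = 0.

    Returns the unique zero-mean divergence-free velocity and zero-mean
    pressure. The spatial integral of the total body force must vanish
    (momentum conservation); a violation raises MomentumViolationError with
    the measured magnitude unless ``compensate_net_force`` is set, in which
    case the mean force density is removed and returned so the caller can
    account for it explicitly (used for substrate-anchored adhesion forces
    whose reaction is absorbed outside the fluid).
    """
    f = np.asarray(force_density, dtype=float)
    shape = tuple(params.grid_shape)
    area = params.domain_size**2
    cell = area / (shape[0] * shape[1])

    net = f.sum(axis=(1, 2)) * cell                       # [pN]
    scale = np.abs(f).sum() * cell
    compensated = np.zeros(2)
    if scale > 0 and np.linalg.norm(net) > params.momentum_rtol * max(scale, 1e-300):
        if not compensate_net_force:
            raise MomentumViolationError(net, scale)
        compensated = net.copy()
        f = f - (net / area)[:, None, None]

    fx = np.fft.fft2(f[0])
    fy = np.fft.fft2(f[1])
    if sigma_p is not None:
        kx, ky = params.wavenumbers()
        sxx = np.fft.fft2(sigma_p[0])
        syy = np.fft.fft2(sigma_p[1])
        sxy = np.fft.fft2(sigma_p[2])
        fx = fx + 1j * kx * sxx + 1j * ky * sxy
        fy = fy + 1j * kx * sxy + 1j * ky * syy
    else:
        kx, ky = params.wavenumbers()

    # zero the Nyquist modes: their odd spectral derivative breaks Hermitian
    # symmetry and would leave a spurious divergence after the real() cast
    nx, ny = shape
    if nx % 2 == 0:
        fx[nx // 2, :] = 0.0
        fy[nx // 2, :] = 0.0
    if ny % 2 == 0:
        fx[:, ny // 2] = 0.0
        fy[:, ny // 2] = 0.0

    k2 = kx**2 + ky**2
    k2[0, 0] = 1.0  # avoid 0/0; zero mode handled explicitly below
    kdotf = kx * fx + ky * fy
    ph = -1j * kdotf / k2
    vxh = (fx - 1j * kx * ph) / (params.eta_f * k2)
    vyh = (fy - 1j * ky * ph) / (params.eta_f * k2)
    vxh[0, 0] = 0.0
    vyh[0, 0] = 0.0
    ph[0, 0] = 0.0

    velocity = np.real(np.stack([np.fft.ifft2(vxh), np.fft.ifft2(vyh)]))
    pressure = np.real(np.fft.ifft2(ph))
    if compensate_net_force:
        return velocity, pressure, compensated
    return velocity, pressure


def _spd_project(k: np.ndarray, L_p: float):
    """Clamp eigenvalues of the symmetric 2x2 field to [floor, inf) and the
    trace below the FENE ceiling. Returns (projected, n_clamped)."""
    a, b, c = k[0], k[1], k[2]
    half = 0.5 * (a + b)
    disc = np.sqrt(np.maximum(0.25 * (a - b) ** 2 + c**2, 0.0))
    lo = half - disc
    hi = half + disc
    lo_c = np.maximum(lo, _EIG_FLOOR)
    clamped = lo < _EIG_FLOOR

    # rebuild with clamped low eigenvalue; eigenvector of `lo`
    out = np.array([a, b, c])
    if np.any(clamped):
        theta = 0.5 * np.arctan2(2.0 * c, a - b)  # eigvec angle of `hi`
        ct, st = np.cos(theta), np.sin(theta)
        na = hi * ct**2 + lo_c * st**2
        nb = hi * st**2 + lo_c * ct**2
        nc = (hi - lo_c) * ct * st
        out[0] = np.where(clamped, na, a)
        out[1] = np.where(clamped, nb, b)
        out[2] = np.where(clamped, nc, c)

    tr = out[0] + out[1]
    ceil = _FENE_CEIL * L_p**2
    over = tr > ceil
    n_over = int(np.count_nonzero(over))
    if n_over:
        s = np.where(over, ceil / np.maximum(tr, 1e-300), 1.0)
        out *= s
    return out, int(np.count_nonzero(clamped)) + n_over


def evolve_conformation(state: FluidState, dt: float) -> int:
    """Advance kappa_p one step; returns the number of safeguard clamps.

    Relaxation, rotation and stretching are stepped with explicit Euler at the
    grid nodes; advection is semi-Lagrangian (periodic bilinear interpolation
    at the backtracked departure points), which is unconditionally stable.
    SPD and the FENE bound are preserved by an eigenvalue floor and trace
    ceiling; every clamp is counted on the state.
    """
    p = state.params
    k = state.conformation
    v = state.velocity

    fac = _fene_factor(k, p.L_p)
    lam = state.relaxation_time
    g = velocity_gradient(v, p)
    gxx, gxy, gyx, gyy = g[0, 0], g[0, 1], g[1, 0], g[1, 1]
    kxx, kyy, kxy = k[0], k[1], k[2]

    # (grad v)^T . k + k . grad v with (grad v)[i,j] = dv_i/dx_j acting as
    # G k + k G^T in matrix form (steady shear dvx/dy=gd gives kxy=lam*gd).
    sxx = 2.0 * (gxx * kxx + gxy * kxy)
    syy = 2.0 * (gyx * kxy + gyy * kyy)
    sxy = gyx * kxx + gyy * kxy + gxx * kxy + gxy * kyy

    rhs = np.empty_like(k)
    rhs[0] = (1.0 - kxx * fac) / lam + sxx
    rhs[1] = (1.0 - kyy * fac) / lam + syy
    rhs[2] = (-kxy * fac) / lam + sxy
    knew = k + dt * rhs

    if np.any(v):
        # semi-Lagrangian departure points in grid units
        h = p.h
        nx, ny = p.grid_shape
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        dx = ix - v[0] * dt / h
        dy = iy - v[1] * dt / h
        coords = np.stack([dx, dy])
        for c in range(3):
            knew[c] = map_coordinates(knew[c], coords, order=1, mode="grid-wrap")

    knew, n_clamp = _spd_project(knew, p.L_p)
    state.conformation = knew
    state.clamp_count += n_clamp
    return n_clamp
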