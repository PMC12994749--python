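"""Regularized-delta kernels coupling Lagrangian nodes to the Eulerian grid.

The 4-point kernel of Peskin is used for both force spreading and velocity
interpolation so the two operations are exact adjoints of one another; this is
what makes the discrete power transferred between structure and fluid
sign-consistent and the spread force density integrate to the nodal force
exactly (partition of unity).
"""

from __future__ import annotations

import numpy as np

__all__ = ["peskin4", "kernel_weights", "spread", "interpolate"]


def peskin4(r: np.ndarray) -> np.ndarray:
    """Peskin 4-point regularized delta, support |r| < 2 (grid units).

    Satisfies sum_j phi(r - j) = 1 and sum_j (r - j) phi(r - j) = 0 for all r,
    so spreading conserves total force and interpolation is exact on constants.
    """
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    out = np.zeros_like(a)
    inner = a <= 1.0
    outer = (a > 1.0) & (a < 2.0)
    ai = a[inner]
    ao = a[outer]
    out[inner] = 0.125 * (3.0 - 2.0 * ai + np.sqrt(1.0 + 4.0 * ai - 4.0 * ai**2))
    out[outer] = 0.125 * (5.0 - 2.0 * ao - np.sqrt(-7.0 + 12.0 * ao - 4.0 * ao**2))
    return out


def kernel_weights(positions: np.ndarray, h: float, shape: tuple[int, int]):
    """Stencil indices and tensor-product weights for each node.

    Returns (ix, iy, w): ix, iy are (N, 4) wrapped grid indices and w is the
    (N, 4, 4) weight array with w.sum(axis=(1, 2)) == 1 to round-off.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    gx = pos[:, 0] / h
    gy = pos[:, 1] / h
    bx = np.floor(gx).astype(np.int64)
    by = np.floor(gy).astype(np.int64)
    offs = np.arange(-1, 3)
    jx = bx[:, None] + offs[None, :]          # (N,4)
    jy = by[:, None] + offs[None, :]
    wx = peskin4(gx[:, None] - jx)
    wy = peskin4(gy[:, None] - jy)
    ix = np.mod(jx, shape[0])
    iy = np.mod(jy, shape[1])
    w = wx[:, :, None] * wy[:, None, :]
    return ix, iy, w


def spread(positions: np.ndarray, forces: np.ndarray, h: float,
           shape: tuple[int, int]) -> np.ndarray:
    """Spread nodal forces [pN] to a grid force density [pN/um^2].

    Nodes are wrapped periodically. The grid integral of the returned density
    equals the vector sum of the nodal forces exactly (up to round-off).
    """
    from ._kernels_numba import spread_core

    pos = np.ascontiguousarray(np.atleast_2d(positions), dtype=np.float64)
    f = np.ascontiguousarray(np.atleast_2d(forces), dtype=np.float64)
    density = np.zeros((2,) + tuple(shape))
    spread_core(pos, f, float(h), shape[0], shape[1], density)
    return density


def interpolate(field: np.ndarray, positions: np.ndarray, h: float) -> np.ndarray:
    """Interpolate a (2, Nx, Ny) grid field to nodes (adjoint of spread)."""
    from ._kernels_numba import interpolate_core

    pos = np.ascontiguousarray(np.atleast_2d(positions), dtype=np.float64)
    out = np.empty_like(pos)
    interpolate_core(np.ascontiguousarray(field, dtype=np.float64), pos,
                     float(h), out)
    return out
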