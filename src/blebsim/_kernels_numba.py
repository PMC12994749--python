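"""Numba-compiled inner loops for the IBM kernel and chain forces.

Pure-python/numpy semantics are defined by the callers; these kernels are
drop-in computational cores. All loops are nopython-compiled and cached.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def _phi4(r):
    a = abs(r)
    if a <= 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    if a < 2.0:
        return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))
    return 0.0


@numba.njit(cache=True)
def spread_core(positions, forces, h, nx, ny, out):
    inv_h2 = 1.0 / (h * h)
    for n in range(positions.shape[0]):
        gx = positions[n, 0] / h
        gy = positions[n, 1] / h
        bx = int(np.floor(gx))
        by = int(np.floor(gy))
        for i in range(-1, 3):
            wx = _phi4(gx - (bx + i))
            ix = (bx + i) % nx
            for j in range(-1, 3):
                w = wx * _phi4(gy - (by + j))
                iy = (by + j) % ny
                out[0, ix, iy] += forces[n, 0] * w * inv_h2
                out[1, ix, iy] += forces[n, 1] * w * inv_h2


@numba.njit(cache=True)
def interpolate_core(field, positions, h, out):
    nx = field.shape[1]
    ny = field.shape[2]
    for n in range(positions.shape[0]):
        gx = positions[n, 0] / h
        gy = positions[n, 1] / h
        bx = int(np.floor(gx))
        by = int(np.floor(gy))
        vx = 0.0
        vy = 0.0
        for i in range(-1, 3):
            wx = _phi4(gx - (bx + i))
            ix = (bx + i) % nx
            for j in range(-1, 3):
                w = wx * _phi4(gy - (by + j))
                iy = (by + j) % ny
                vx += field[0, ix, iy] * w
                vy += field[1, ix, iy] * w
        out[n, 0] = vx
        out[n, 1] = vy


@numba.njit(cache=True)
def segment_tension_core(positions, tension, mask, out):
    """Nodal forces from per-segment tensions; segment i joins nodes i, i+1.

    Returns -1.0 on a degenerate segment (caller raises)."""
    n = positions.shape[0]
    ok = 1.0
    for i in range(n):
        j = (i + 1) % n
        dx = positions[j, 0] - positions[i, 0]
        dy = positions[j, 1] - positions[i, 1]
        L = np.sqrt(dx * dx + dy * dy)
        if L < 1e-12:
            ok = -1.0
            continue
        if not mask[i]:
            continue
        fx = tension[i] * dx / L
        fy = tension[i] * dy / L
        out[i, 0] += fx
        out[i, 1] += fy
        out[j, 0] -= fx
        out[j, 1] -= fy
    return ok


@numba.njit(cache=True)
def cortex_forces_core(positions, rest_lengths, alive, n_act, n_myo,
                       velocities, kappa_c, f_myo, v_myo, signal, out):
    """Elastic + active (force-velocity limited) cortex chain forces."""
    n = positions.shape[0]
    for i in range(n):
        j = (i + 1) % n
        if not (alive[i] and alive[j]):
            continue
        dx = positions[j, 0] - positions[i, 0]
        dy = positions[j, 1] - positions[i, 1]
        L = np.sqrt(dx * dx + dy * dy)
        if L < 1e-12:
            continue
        tx = dx / L
        ty = dy / L
        n_act_seg = 0.5 * (n_act[i] + n_act[j])
        T_el = kappa_c * n_act_seg * (L - rest_lengths[i])
        n_myo_seg = 0.5 * (n_myo[i] + n_myo[j])
        v_short = -((velocities[j, 0] - velocities[i, 0]) * tx
                    + (velocities[j, 1] - velocities[i, 1]) * ty)
        fv = 1.0 - v_short / v_myo
        if fv < 0.0:
            fv = 0.0
        elif fv > 1.5:
            fv = 1.5
        T = T_el + f_myo * n_myo_seg * signal * fv
        fx = T * tx
        fy = T * ty
        out[i, 0] += fx
        out[i, 1] += fy
        out[j, 0] -= fx
        out[j, 1] -= fy


@numba.njit(cache=True)
def linker_core(mem_pos, cor_pos, bound, stiffness, rest_length,
                f_mem, f_cor):
    n = mem_pos.shape[0]
    for i in range(n):
        dx = cor_pos[i, 0] - mem_pos[i, 0]
        dy = cor_pos[i, 1] - mem_pos[i, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        ext = dist - rest_length
        if ext <= 0.0 or dist < 1e-12:
            f_mem[i, 0] = 0.0
            f_mem[i, 1] = 0.0
            f_cor[i, 0] = 0.0
            f_cor[i, 1] = 0.0
            continue
        mag = stiffness * bound[i] * ext / dist
        f_mem[i, 0] = mag * dx
        f_mem[i, 1] = mag * dy
        f_cor[i, 0] = -mag * dx
        f_cor[i, 1] = -mag * dy
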