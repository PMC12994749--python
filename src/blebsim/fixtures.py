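"""Synthetic input generators for tests and examples.

All fixtures are generated programmatically from a seed: initial circular
cell geometries, Brownian/ballistic track sets with known motility
parameters, and bleb event logs with prescribed frequency and angle
statistics.
"""

from __future__ import annotations

import numpy as np

from .kinetics import BlebEventLog
from .structures import MembraneState
from .tracks import TrackSet

__all__ = ["make_fixture", "brownian_tracks", "ballistic_tracks",
           "synthetic_event_log"]


def brownian_tracks(D: float, n_cells: int, n_steps: int, dt: float,
                    seed: int) -> TrackSet:
    """2D random walks with diffusion coefficient D [um^2/min].

    Step variance per axis is 2 D dt (D converted to um^2/s)."""
    rng = np.random.default_rng(seed)
    D_s = D / 60.0
    sigma = np.sqrt(2.0 * D_s * dt)
    t = dt * np.arange(n_steps + 1)
    times, positions = [], []
    for _ in range(n_cells):
        steps = rng.normal(0.0, sigma, size=(n_steps, 2))
        x = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        times.append(t)
        positions.append(x)
    return TrackSet.from_arrays(times, positions)


def ballistic_tracks(speed: float, n_cells: int, n_steps: int, dt: float,
                     seed: int) -> TrackSet:
    """Straight-line tracks at constant speed [um/s] in random directions."""
    rng = np.random.default_rng(seed)
    t = dt * np.arange(n_steps + 1)
    times, positions = [], []
    for _ in range(n_cells):
        ang = rng.uniform(0, 2 * np.pi)
        v = speed * np.array([np.cos(ang), np.sin(ang)])
        positions.append(np.outer(t, v))
        times.append(t)
    return TrackSet.from_arrays(times, positions)


def synthetic_event_log(frequency: float, duration: float, seed: int,
                        angles: str = "uniform") -> BlebEventLog:
    """Event log at a prescribed mean frequency [1/s]; angles drawn uniform
    on the circle (expected consecutive wrapped separation 90 deg) or fixed."""
    rng = np.random.default_rng(seed)
    n = int(round(frequency * duration))
    t = np.sort(rng.uniform(0.0, duration, size=n))
    log = BlebEventLog()
    for ti in t:
        if angles == "uniform":
            a = rng.uniform(-np.pi, np.pi)
        else:
            a = 0.0
        log.append(float(ti), float(a), 1.0)
    return log


def make_fixture(kind: str, seed: int = 0, **kw):
    """Dispatch: 'circle_cell', 'brownian_tracks', 'ballistic_tracks',
    'event_log'."""
    if kind == "circle_cell":
        n = kw.get("n_nodes", 128)
        r = kw.get("radius", 10.0)
        c = kw.get("center", (40.0, 40.0))
        return MembraneState.circle(n, r, c)
    if kind == "brownian_tracks":
        return brownian_tracks(kw.get("D", 1.0), kw.get("n_cells", 100),
                               kw.get("n_steps", 200), kw.get("dt", 1.0), seed)
    if kind == "ballistic_tracks":
        return ballistic_tracks(kw.get("speed", 0.1), kw.get("n_cells", 10),
                                kw.get("n_steps", 200), kw.get("dt", 1.0), seed)
    if kind == "event_log":
        return synthetic_event_log(kw.get("frequency", 4.0),
                                   kw.get("duration", 10.0), seed,
                                   angles=kw.get("angles", "uniform"))
    raise ValueError(f"unknown fixture kind {kind!r}")
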