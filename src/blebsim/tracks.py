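"""Motility statistics from cell tracks and bleb event logs.

Implements the standard random-motility toolkit: time-averaged and ensemble
mean squared displacement (MSD), the effective motility coefficient D_eff
from an origin-constrained linear MSD fit (default window 16 s, 2D
convention D = slope/4), bleb nucleation frequency nu_bleb and the mean
polar angle between consecutive nucleation events p_bleb, the run-based
estimate D_cell = d_run^2/(4 t_run), and first-passage walking speeds with
an MSD-threshold motile classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import BlebEventLog, wrapped_angle_difference_deg

__all__ = ["TrackSet", "MotilitySummary", "msd", "fit_Deff", "bleb_stats",
           "motility_from_runs", "walking_speed"]


@dataclass
class TrackSet:
    """Per-cell centroid time series.

    ``table`` columns: cell_id, t_s, x_um, y_um. Tracks must have >= 2
    points each; time stamps are per-track."""

    table: pd.DataFrame
    diameter: float | None = None     # [um]

    def __post_init__(self):
        need = {"cell_id", "t_s", "x_um", "y_um"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        counts = self.table.groupby("cell_id").size()
        if (counts < 2).any():
            raise ValueError("every track needs at least 2 points")

    @classmethod
    def from_arrays(cls, times_list, positions_list, ids=None,
                    diameter=None) -> "TrackSet":
        frames = []
        for i, (t, x) in enumerate(zip(times_list, positions_list)):
            cid = ids[i] if ids is not None else i
            frames.append(pd.DataFrame({"cell_id": cid, "t_s": np.asarray(t),
                                        "x_um": np.asarray(x)[:, 0],
                                        "y_um": np.asarray(x)[:, 1]}))
        return cls(pd.concat(frames, ignore_index=True), diameter=diameter)

    @classmethod
    def read_csv(cls, path, diameter=None) -> "TrackSet":
        return cls(pd.read_csv(path), diameter=diameter)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def cells(self):
        for cid, grp in self.table.groupby("cell_id", sort=False):
            g = grp.sort_values("t_s")
            yield cid, g["t_s"].to_numpy(), g[["x_um", "y_um"]].to_numpy()


@dataclass
class MotilitySummary:
    D_eff: float | None = None            # [um^2/min]
    nu_bleb: float | None = None          # [1/s]
    p_bleb: float | None = None           # [deg]
    D_cell: float | None = None           # [um^2/min]
    walking_speeds: dict = field(default_factory=dict)   # cell_id -> um/s
    motile_fraction: float | None = None


def _track_msd(t: np.ndarray, x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one uniformly sampled track at the given lags [s]."""
    dt = t[1] - t[0]
    out = np.full(len(lags), np.nan)
    for j, lag in enumerate(lags):
        k = int(round(lag / dt))
        if k < 1 or k >= len(t):
            continue
        d = x[k:] - x[:-k]
        out[j] = float(np.mean(np.sum(d**2, axis=1)))
    return out


def msd(tracks: TrackSet, lags) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell time-averaged MSD and the ensemble mean at each lag [um^2].

    Returns (per_cell, ensemble): a DataFrame indexed by lag with one column
    per cell, and the row-wise nan-mean."""
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag set")
    cols = {}
    for cid, t, x in tracks.cells():
        cols[cid] = _track_msd(t, x, lags)
    per_cell = pd.DataFrame(cols, index=pd.Index(lags, name="lag_s"))
    ensemble = np.nanmean(per_cell.to_numpy(), axis=1)
    return per_cell, ensemble


def fit_Deff(lags, msd_values, window: float = 16.0,
             msd_dim_factor: float = 4.0) -> float:
    """Origin-constrained least-squares slope of MSD over [0, window] s;
    D_eff = slope / msd_dim_factor, reported in um^2/min."""
    lags = np.asarray(lags, dtype=float)
    vals = np.asarray(msd_values, dtype=float)
    keep = (lags > 0) & (lags <= window) & np.isfinite(vals)
    if np.count_nonzero(keep) < 2:
        raise ValueError("fewer than 2 MSD points inside the fit window")
    tau, m = lags[keep], vals[keep]
    slope = float(np.sum(tau * m) / np.sum(tau**2))     # [um^2/s]
    return slope / msd_dim_factor * 60.0


def bleb_stats(log: BlebEventLog, duration: float):
    """Bleb nucleation frequency [1/s] and mean consecutive-event polar
    angle [deg] (wrapped to [0, 180]); p_bleb is None for < 2 events."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    nu = len(log) / duration
    if len(log) < 2:
        return nu, None
    ang = np.degrees(np.asarray(log.angles))
    diffs = wrapped_angle_difference_deg(ang[1:], ang[:-1])
    return nu, float(np.mean(diffs))


def motility_from_runs(d_run: float, t_run: float) -> float:
    """Run-based motility estimate D_cell = d_run^2 / (4 t_run) in um^2/min
    (d_run in um, t_run in s)."""
    if t_run <= 0:
        raise ValueError("t_run must be positive")
    return d_run**2 / (4.0 * t_run) * 60.0


def walking_speed(tracks: TrackSet, diameter: float,
                  msd_threshold_lag: float = 3000.0):
    """First-passage walking speed and MSD-threshold motile classification.

    Speed: cell diameter divided by the first time the net displacement from
    the track start reaches one diameter (None if never reached). Motile:
    the per-cell time-averaged MSD exceeds diameter^2 at some lag <=
    msd_threshold_lag."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    speeds: dict = {}
    motile: dict = {}
    for cid, t, x in tracks.cells():
        disp = np.linalg.norm(x - x[0], axis=1)
        hit = np.flatnonzero(disp >= diameter)
        if len(hit) and t[hit[0]] > t[0]:
            speeds[cid] = diameter / (t[hit[0]] - t[0])
        else:
            speeds[cid] = None
        dt = t[1] - t[0]
        max_k = min(len(t) - 1, int(msd_threshold_lag / dt))
        lags = dt * np.arange(1, max_k + 1)
        m = _track_msd(t, x, lags) if max_k >= 1 else np.array([])
        motile[cid] = bool(np.any(m > diameter**2))
    frac = float(np.mean([motile[c] for c in motile])) if motile else 0.0
    return speeds, motile, frac


def summarize(tracks: TrackSet, log: BlebEventLog | None = None,
              duration: float | None = None, window: float = 16.0,
              diameter: float | None = None) -> MotilitySummary:
    """Convenience wrapper computing the full summary for one experiment."""
    t0 = next(iter(tracks.cells()))[1]
    dt = t0[1] - t0[0]
    lags = dt * np.arange(1, len(t0))
    _, ens = msd(tracks, lags)
    out = MotilitySummary()
    try:
        out.D_eff = fit_Deff(lags, ens, window=window)
    except ValueError:
        pass
    if log is not None and duration:
        out.nu_bleb, out.p_bleb = bleb_stats(log, duration)
    dia = diameter or tracks.diameter
    if dia:
        speeds, motile, frac = walking_speed(tracks, dia)
        out.walking_speeds = speeds
        out.motile_fraction = frac
    return out


def plot_msd(lags, msd_values, path, per_cell=None):
    """Write an MSD-vs-lag figure (log-log) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    if per_cell is not None:
        for col in per_cell.columns:
            ax.plot(per_cell.index, per_cell[col], color="0.8", lw=0.8)
    ax.plot(lags, msd_values, "k-", lw=2, label="ensemble mean")
    ax.set_xlabel("lag [s]")
    ax.set_ylabel(r"MSD [$\mu m^2$]")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_wind_rose(tracks: TrackSet, path):
    """Write a wind-rose of track displacements (origin-aligned) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    for _, t, x in tracks.cells():
        ax.plot(x[:, 0] - x[0, 0], x[:, 1] - x[0, 1], lw=0.8)
    ax.set_xlabel(r"x [$\mu m$]")
    ax.set_ylabel(r"y [$\mu m$]")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
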