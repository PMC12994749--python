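"""Snapshot, trajectory and manifest output.

Field and structure snapshots go to one HDF5 container per run; trajectories
and bleb events to CSV; a JSON manifest records the full parameter set, the
seed and the package version so any run can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from .simulator import Cell, Trajectory


def write_snapshot(path, cell: Cell, label: str | None = None) -> None:
    """Append one full-state snapshot to an HDF5 container."""
    import h5py

    label = label if label is not None else f"t_{cell.time:.6f}"
    with h5py.File(path, "a") as f:
        g = f.require_group(label)
        g.attrs["time_s"] = cell.time
        g.attrs["domain_size_um"] = cell.fluid.params.domain_size
        g.attrs["grid_shape"] = cell.fluid.params.grid_shape
        for name, arr in (
            ("velocity", cell.fluid.velocity),
            ("pressure", cell.fluid.pressure),
            ("conformation", cell.fluid.conformation),
            ("material", cell.fluid.polymer_viscosity),
            ("membrane/positions", cell.membrane.positions),
            ("cortex/positions", cell.cortex.positions),
            ("cortex/n_act", cell.cortex.n_act),
            ("cortex/n_myo", cell.cortex.n_myo),
            ("linkers/bound", cell.linkers.bound),
        ):
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(arr))


def write_trajectory_csv(path, trajectory: Trajectory) -> None:
    trajectory.to_dataframe().to_csv(path, index=False)


def write_events_csv(path, bleb_log) -> None:
    bleb_log.to_dataframe().to_csv(path, index=False)


def write_manifest(outdir, config: dict, seed, extra: dict | None = None) -> Path:
    """Write the run manifest (parameters + seed + version + wall times)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    manifest = {
        "package": "blebsim",
        "version": __version__,
        "seed": seed,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _clean(config),
    }
    if extra:
        manifest.update(_clean(extra))
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
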