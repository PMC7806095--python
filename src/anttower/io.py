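"""Run persistence: config files, manifests, tables and array stores.

Every CLI subcommand writes a run directory containing a JSON manifest
(all parameters, seed, package version, artifact paths), comma-separated
tables with headers for all statistics, and ``.npz`` archives for
height-map stacks.  Everything written here can be re-read into the
in-memory objects it came from.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import SimulationParams
from .simulator import RunResult

__all__ = [
    "load_config",
    "write_manifest",
    "read_manifest",
    "save_run",
    "load_run_series",
]


def load_config(path) -> dict:
    """Flat key-value config file (YAML mapping of parameter names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return data


def write_manifest(outdir: Path, params: SimulationParams, artifacts: dict,
                   extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "package": "anttower",
        "version": __version__,
        "params": params.to_dict(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    if extra:
        doc.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> dict:
    doc = json.loads(Path(path).read_text())
    doc["params"] = SimulationParams(**doc["params"])
    return doc


def save_run(result: RunResult, outdir) -> Path:
    """Persist a run: series CSV, optional snapshot stack, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    series_path = outdir / "series.csv"
    result.series.to_csv(series_path, index=False)
    artifacts["series"] = series_path.name
    if result.snapshots is not None:
        snap_path = outdir / "snapshots.npz"
        np.savez_compressed(
            snap_path,
            times=np.array([t for t, _hm, _s in result.snapshots]),
            heights=np.stack([hm for _t, hm, _s in result.snapshots]),
            states=np.stack([s for _t, _hm, s in result.snapshots]),
        )
        artifacts["snapshots"] = snap_path.name
    final_path = outdir / "final_state.npz"
    w = result.world
    np.savez_compressed(
        final_path,
        height=w.height,
        agent_x=w.agent_x,
        agent_y=w.agent_y,
        agent_z=w.agent_z,
        locked=w.locked,
        t=np.int64(w.t),
    )
    artifacts["final_state"] = final_path.name
    return write_manifest(outdir, result.params, artifacts)


def load_run_series(outdir) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "series.csv")
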