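"""Readers and writers for run artifacts.

A trajectory is stored as one delimited table per snapshot (columns x, S,
T_A, T_M, L, M) next to a YAML manifest recording the parameters, grid,
tolerances and snapshot times, so a run directory is self-describing and
re-executable from the manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import FIELD_NAMES, Grid1D, StateFields
from .params import DimensionlessParams
from .solver import SolverSettings, Trajectory

SNAPSHOT_COLUMNS = ("x",) + FIELD_NAMES
MANIFEST_NAME = "manifest.yaml"


class ArtifactError(RuntimeError):
    """A run artifact is missing, truncated or inconsistent."""


def _snapshot_name(index: int) -> str:
    return f"snapshot_{index:04d}.csv"


def write_trajectory(traj: Trajectory, outdir: str | Path, extra_manifest: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = traj.grid.x
    for i, (t, state) in enumerate(zip(traj.times, traj.states)):
        df = pd.DataFrame({"x": x, **{n: getattr(state, n) for n in FIELD_NAMES}})
        df.to_csv(outdir / _snapshot_name(i), index=False)
    params = {k: v for k, v in asdict(traj.params).items() if k != "regime_warnings"}
    manifest = {
        "times": [float(t) for t in traj.times],
        "params": params,
        "grid": {"n_points": traj.grid.n_points, "length": traj.grid.length},
        "solver": {
            "rel_tol": traj.settings.rel_tol,
            "abs_tol": traj.settings.abs_tol,
            "stabilisation_rate": traj.settings.stabilisation_rate,
            "extinction_threshold": traj.settings.extinction_threshold,
            "snapshot_times": [float(t) for t in traj.settings.snapshot_times],
        },
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (outdir / MANIFEST_NAME).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def read_trajectory(rundir: str | Path) -> Trajectory:
    rundir = Path(rundir)
    mpath = rundir / MANIFEST_NAME
    if not mpath.exists():
        raise ArtifactError(f"no manifest in {rundir}")
    manifest = yaml.safe_load(mpath.read_text())
    try:
        times = np.asarray(manifest["times"], dtype=float)
        params = DimensionlessParams(**manifest["params"])
        grid = Grid1D(**manifest["grid"])
        settings = SolverSettings(
            rel_tol=manifest["solver"]["rel_tol"],
            abs_tol=manifest["solver"]["abs_tol"],
            stabilisation_rate=manifest["solver"]["stabilisation_rate"],
            extinction_threshold=manifest["solver"].get("extinction_threshold", 1e-12),
            snapshot_times=manifest["solver"]["snapshot_times"],
        )
    except (KeyError, TypeError) as exc:
        raise ArtifactError(f"corrupt manifest {mpath}: {exc}") from exc
    states = []
    for i, t in enumerate(times):
        spath = rundir / _snapshot_name(i)
        if not spath.exists():
            raise ArtifactError(f"missing snapshot file {spath}")
        try:
            df = pd.read_csv(spath)
        except Exception as exc:
            raise ArtifactError(f"cannot read snapshot {spath}: {exc}") from exc
        if list(df.columns) != list(SNAPSHOT_COLUMNS) or len(df) != grid.n_points:
            raise ArtifactError(f"corrupt snapshot {spath}: wrong columns or row count")
        states.append(StateFields(**{n: df[n].to_numpy() for n in FIELD_NAMES}))
    return Trajectory(times, states, params, grid, settings)


def write_steady_state_report(states, path: str | Path) -> Path:
    """One row per homogeneous steady state, with a 'free' marker for M."""
    rows = []
    for ss in states:
        rows.append(
            {
                "label": ss.label,
                "S": ss.S,
                "T_A": ss.T_A,
                "T_M": ss.T_M,
                "L": ss.L,
                "M": "free" if ss.m_free else ss.M,
                "feasible": ss.feasible,
                "stability": ss.stability,
                "nonmatrix_stability": ss.nonmatrix_stability,
                "leading_eigenvalue_real_part": ss.leading_eigenvalue_real_part,
                "note": ss.note,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_sweep_table(records, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)
    return path


def read_sweep_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
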