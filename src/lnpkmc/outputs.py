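"""Serialization of trajectories, sweep tables and reports.

All files are plain text (CSV/JSON/YAML), written atomically (temp file +
rename), with 12-significant-digit numeric formatting, ``\\n`` newlines and
UTF-8 encoding so that identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationTrajectory
from .ml_design import FEATURE_COLUMNS, OUTPUT_COLUMNS, ImportanceReport

__all__ = ["write_outputs", "read_trajectory_dir"]

_FLOAT_FMT = "%.12g"


def _atomic_write(path: Path, text: str):
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format=_FLOAT_FMT,
                     lineterminator="\n")


def _json(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n"


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _population_frame(pop) -> pd.DataFrame:
    return pd.DataFrame({
        "id": pop.ids,
        "units": pop.units,
        "rna_count": pop.rna,
        "radius_nm": pop.radii,
        "phi_peg": pop.phi_peg,
        "psi0": pop.psi if pop.psi is not None else np.nan,
    })


def write_outputs(obj, directory, manifest: dict = None) -> list:
    """Write an object's file set into ``directory``; returns paths written.

    Trajectories produce ``snapshots.csv``, ``events.csv``,
    ``final_population.csv`` (plus ``particles.csv`` when per-snapshot
    dumps were recorded) and ``manifest.json``; sweep tables produce
    ``sweep.csv`` with a JSON schema sidecar; importance reports produce
    ``importance.json``.
    """
    directory = Path(directory)
    written = []

    def put(name, text):
        path = directory / name
        _atomic_write(path, text)
        written.append(path)

    if isinstance(obj, SimulationTrajectory):
        put("snapshots.csv", _csv(obj.snapshots))
        put("events.csv", _csv(obj.events))
        put("final_population.csv", _csv(_population_frame(obj.final)))
        if obj.particles is not None:
            put("particles.csv", _csv(obj.particles))
        info = dict(manifest or {})
        info.setdefault("seed", obj.seed)
        info["run"] = dict(obj.meta)
        info["run"]["lipids_per_unit"] = obj.final.lipids_per_unit
        put("manifest.json", _json(info))
    elif isinstance(obj, pd.DataFrame):
        put("sweep.csv", _csv(obj))
        schema = {
            "columns": {c: str(obj[c].dtype) for c in obj.columns},
            "features": list(FEATURE_COLUMNS),
            "outputs": list(OUTPUT_COLUMNS),
        }
        put("sweep.schema.json", _json(schema))
        if manifest:
            put("manifest.json", _json(manifest))
    elif isinstance(obj, ImportanceReport):
        put("importance.json", _json({
            "target": obj.target,
            "importances": obj.importances,
            "cv_rmse": obj.cv_rmse,
            "hyperparameters": obj.hyperparameters,
            "seed": obj.seed,
            "degenerate": obj.degenerate,
            **({"manifest": manifest} if manifest else {}),
        }))
    elif isinstance(obj, (list, tuple)) and all(
            isinstance(r, ImportanceReport) for r in obj):
        put("importance.json", _json({
            r.target: {
                "importances": r.importances,
                "cv_rmse": r.cv_rmse,
                "hyperparameters": r.hyperparameters,
                "seed": r.seed,
                "degenerate": r.degenerate,
            } for r in obj
        }))
        if manifest:
            put("manifest.json", _json(manifest))
    else:
        raise TypeError(f"don't know how to serialize {type(obj)}")
    return written


def read_trajectory_dir(directory) -> dict:
    """Read back a simulate output directory into DataFrames + manifest."""
    directory = Path(directory)
    out = {
        "snapshots": pd.read_csv(directory / "snapshots.csv"),
        "events": pd.read_csv(directory / "events.csv"),
        "final_population": pd.read_csv(directory / "final_population.csv"),
    }
    mpath = directory / "manifest.json"
    if mpath.exists():
        out["manifest"] = json.loads(mpath.read_text())
    ppath = directory / "particles.csv"
    if ppath.exists():
        out["particles"] = pd.read_csv(ppath)
    return out
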