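"""Readers, writers and run-configuration sidecars.

Cell-record tables are plain CSV (comma-separated, UTF-8, '.' decimal,
header required; booleans as 0/1; missing values empty).  Lengths are in
micrometres in record tables and nanometres in meshes; units are embedded in
column names.  Meshes are PLY or OBJ triangle meshes, loaded through
trimesh.  Every writer can emit a JSON sidecar holding the fully resolved
configuration and seed, so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .cohorts import MEASUREMENT_COLUMNS

__all__ = [
    "RECORD_COLUMNS",
    "read_cell_records",
    "write_cell_records",
    "read_mesh",
    "write_mesh",
    "read_path_csv",
    "write_report",
    "write_sidecar",
]

#: Canonical column order of the cell-record CSV schema.
RECORD_COLUMNS = (
    "cell_id",
    "n_flagella",
    "n_kinetoplasts",
    "n_nuclei",
    "tip_marker",
    "mid_marker",
    *MEASUREMENT_COLUMNS,
)

_COUNT_COLUMNS = ("n_flagella", "n_kinetoplasts", "n_nuclei")
_MARKER_COLUMNS = ("tip_marker", "mid_marker")


def read_cell_records(path) -> pd.DataFrame:
    """Read and validate a cell-record CSV.

    Rows violating the record invariants (counts < 1, negative lengths, free
    flagellum longer than the flagellum, both markers on a 1F1K1N cell) are
    reported with their line numbers in a single ValueError.  An empty file
    yields an empty table with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty record table",
                      UserWarning, stacklevel=2)
        return pd.DataFrame(columns=list(RECORD_COLUMNS))

    missing = [c for c in RECORD_COLUMNS if c not in df.columns
               and c not in MEASUREMENT_COLUMNS]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    problems: list[str] = []

    def line(i) -> int:  # header is line 1
        return int(i) + 2

    for col in _COUNT_COLUMNS + _MARKER_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        problems += [f"line {line(i)}: non-numeric {col}" for i in bad]
    if problems:
        raise ValueError(f"{path}: invalid records:\n" + "\n".join(problems))

    for col in MEASUREMENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        problems += [f"line {line(i)}: non-numeric {col}" for i in bad]
        df[col] = coerced
        neg = df.index[coerced < 0]
        problems += [f"line {line(i)}: negative {col}" for i in neg]

    for col in _COUNT_COLUMNS:
        bad = df.index[df[col].astype(int) < 1]
        problems += [f"line {line(i)}: {col} < 1" for i in bad]

    over = df.index[
        df["free_flagellum_um"].notna()
        & df["flagellum_um"].notna()
        & (df["free_flagellum_um"] > df["flagellum_um"] + 1e-9)
    ]
    problems += [f"line {line(i)}: free flagellum exceeds flagellum length"
                 for i in over]

    g1 = (df["n_flagella"] == 1) & (df["n_kinetoplasts"] == 1) & (df["n_nuclei"] == 1)
    both = df.index[g1 & df["tip_marker"].astype(bool) & df["mid_marker"].astype(bool)]
    problems += [f"line {line(i)}: both FCR markers set on a 1F1K1N cell"
                 for i in both]

    if problems:
        raise ValueError(f"{path}: invalid records:\n" + "\n".join(problems))
    return df


def write_cell_records(df: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a record table in the canonical column order (markers as 0/1)."""
    out = df.copy()
    for col in _MARKER_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    cols = [c for c in RECORD_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False)
    if sidecar is not None:
        write_sidecar(path, sidecar)


def read_mesh(path) -> trimesh.Trimesh:
    """Load a PLY/OBJ triangle mesh with outward normals.

    Quads are triangulated by trimesh; dangling vertex indices or non-mesh
    content raise ValueError.  Watertightness is *not* enforced here (the
    caliber measurement enforces it) but is available as ``mesh.is_watertight``.
    """
    loaded = trimesh.load(str(path), force="mesh")
    if not isinstance(loaded, trimesh.Trimesh) or loaded.faces.shape[0] == 0:
        raise ValueError(f"{path}: not a triangle mesh")
    if loaded.faces.max() >= len(loaded.vertices):
        raise ValueError(f"{path}: face indices out of range")
    if loaded.is_watertight:
        trimesh.repair.fix_normals(loaded)
    return loaded


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh; format chosen from the extension (.ply / .obj)."""
    mesh.export(str(path))


def read_path_csv(path) -> np.ndarray:
    """Read an anterior-path polyline CSV with columns x_nm, y_nm, z_nm."""
    df = pd.read_csv(path)
    cols = ["x_nm", "y_nm", "z_nm"]
    if not all(c in df.columns for c in cols):
        raise ValueError(f"{path}: path CSV needs columns {cols}")
    return df[cols].to_numpy(dtype=float)


def write_report(frame: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a tidy report/summary CSV with deterministic row and column order.

    Emits a ``<path>.config.json`` sidecar when ``config`` is given; with the
    same inputs and seed the output is byte-identical.
    """
    out = frame.copy()
    sort_cols = [c for c in ("time_u", "parameter", "cohort", "stage",
                             "old_label_class") if c in out.columns]
    if sort_cols:
        out = out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False)
    if config is not None:
        write_sidecar(path, config)


def write_sidecar(path, config: dict) -> Path:
    """Write the resolved run configuration next to an output file."""
    sidecar = Path(str(path) + ".config.json")
    sidecar.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return sidecar
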