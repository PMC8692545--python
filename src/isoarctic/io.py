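"""Format plumbing: trajectory and cell-series CSV, optional NetCDF grids,
and the run manifest."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import CellSeries
from .boxmodel import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory_frame",
    "write_cells",
    "read_cells_csv",
    "read_cells_netcdf",
    "cells_from_trajectory",
    "write_manifest",
]

CELL_VARIABLES = ("salinity", "nstar", "pom", "d15n_pom")


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> Path:
    """Write a trajectory as long CSV with a stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "trajectory.csv"
    df = traj.data.sort_values(["year", "box", "variable"], kind="mergesort")
    df.to_csv(path, index=False, columns=["year", "box", "variable", "value"])
    return path


def read_trajectory_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"year", "box", "variable", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(expected)}")
    return df


def write_cells(cells: list[CellSeries], path: str | Path) -> Path:
    """Write cells as long CSV (cell_id, year, variable, value)."""
    rows = []
    for c in cells:
        for var in CELL_VARIABLES:
            for y, v in zip(c.years, getattr(c, var)):
                rows.append((c.cell_id, int(y), var, float(v)))
    df = pd.DataFrame(rows, columns=["cell_id", "year", "variable", "value"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _cells_from_frame(df: pd.DataFrame) -> list[CellSeries]:
    have = set(df["variable"].unique())
    if {"no3", "po4"}.issubset(have) and "nstar" not in have:
        wide = df.pivot_table(index=["cell_id", "year"], columns="variable",
                              values="value").reset_index()
        wide["nstar"] = wide["no3"] - 16.0 * wide["po4"]
        df = wide.melt(id_vars=["cell_id", "year"], var_name="variable",
                       value_name="value")
        have = set(df["variable"].unique())
    missing = set(CELL_VARIABLES) - have
    if missing:
        raise ValueError(
            f"input lacks variables {sorted(missing)}; expected "
            f"{list(CELL_VARIABLES)} (or no3+po4 in place of nstar)"
        )
    cells = []
    for cell_id, grp in df[df["variable"].isin(CELL_VARIABLES)].groupby("cell_id"):
        wide = grp.pivot(index="year", columns="variable", values="value").sort_index()
        cells.append(CellSeries(
            cell_id=str(cell_id),
            years=wide.index.to_numpy(),
            salinity=wide["salinity"].to_numpy(),
            nstar=wide["nstar"].to_numpy(),
            pom=wide["pom"].to_numpy(),
            d15n_pom=wide["d15n_pom"].to_numpy(),
        ))
    return cells


def read_cells_csv(path: str | Path) -> list[CellSeries]:
    df = pd.read_csv(path)
    expected = {"cell_id", "year", "variable", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"cell CSV must have columns {sorted(expected)}")
    return _cells_from_frame(df)


def read_cells_netcdf(path: str | Path, min_lat: float = 50.0) -> list[CellSeries]:
    """Read a CF-style (time, lat, lon) grid, masking cells south of min_lat.

    Requires xarray (scipy engine, NetCDF3).  Variables: salinity, pom,
    d15n_pom, and nstar or no3+po4.
    """
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    if "nstar" not in ds and {"no3", "po4"}.issubset(ds.variables):
        ds = ds.assign(nstar=ds["no3"] - 16.0 * ds["po4"])
    missing = set(CELL_VARIABLES) - set(ds.variables)
    if missing:
        raise ValueError(f"NetCDF input lacks variables {sorted(missing)}")
    years = ds["time"].values
    if np.issubdtype(years.dtype, np.datetime64):
        years = pd.DatetimeIndex(years).year.to_numpy()
    cells = []
    for lat in ds["lat"].values:
        if lat < min_lat:
            continue
        for lon in ds["lon"].values:
            sel = ds.sel(lat=lat, lon=lon)
            arrays = {v: np.asarray(sel[v].values, dtype=float)
                      for v in CELL_VARIABLES}
            if any(np.all(np.isnan(a)) for a in arrays.values()):
                continue
            cells.append(CellSeries(
                cell_id=f"lat{lat:.2f}_lon{lon:.2f}",
                years=np.asarray(years, dtype=int),
                **arrays,
            ))
    return cells


def cells_from_trajectory(traj_frame: pd.DataFrame) -> list[CellSeries]:
    """Treat each box of a trajectory as one cell for attribution."""
    df = traj_frame[traj_frame["variable"].isin(
        ("salinity", "nstar", "pon", "d15n_pom"))].copy()
    df["variable"] = df["variable"].replace({"pon": "pom"})
    df = df.rename(columns={"box": "cell_id"})
    return _cells_from_frame(df)


def write_manifest(out_dir: str | Path, **fields) -> Path:
    """Write the run manifest; the parameter hash makes configs diffable."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "isoarctic",
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        **fields,
    }
    blob = json.dumps({k: v for k, v in manifest.items() if k != "created"},
                      sort_keys=True, default=str).encode()
    manifest["manifest_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
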