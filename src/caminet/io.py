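"""Reading CNMF-style stores and plain tables; spreadsheet/CSV export.

Labeled-array stores follow the Minian convention: a zarr directory or a
NetCDF file holding a 2-D trace variable (default ``"C"``, unit × frame)
and optionally either a 3-D footprint variable (default ``"A"``, unit ×
height × width) or per-unit ``x``/``y`` centroid variables.  Footprints are
reduced to intensity-weighted centroids on load — point positions are the
canonical representation downstream.

Plain-table input: a traces CSV whose first column is ``unit_id`` and
remaining columns are frames, plus an optional positions CSV with columns
``unit_id, x, y``.

Reports are written as one ``.xlsx`` workbook with one sheet per table,
each table mirrored as a CSV next to the workbook.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .core import NeuronPositions, Recording, TraceMatrix

__all__ = [
    "read_labeled_store",
    "write_labeled_store",
    "read_table",
    "write_table",
    "write_report",
]


class FormatError(ValueError):
    """A store or table does not match the expected layout."""


def _interpolate_short_gaps(traces: np.ndarray, unit_ids: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly interpolate isolated NaN gaps of at most ``max_gap`` frames."""
    out = traces.copy()
    for i in range(out.shape[0]):
        row = out[i]
        isnan = np.isnan(row)
        if not isnan.any():
            continue
        if isnan.all():
            raise FormatError(f"unit {unit_ids[i]}: all frames NaN")
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.astype(int), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s > max_gap:
                raise FormatError(f"unit {unit_ids[i]}: NaN gap of {e - s} frames exceeds {max_gap}")
        idx = np.arange(len(row))
        row[isnan] = np.interp(idx[isnan], idx[~isnan], row[~isnan])
    return out


def _centroids(footprints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted centroid of each unit's footprint.

    The first spatial axis index is reported as x, the second as y.
    """
    w = np.abs(np.asarray(footprints, dtype=float))
    totals = w.sum(axis=(1, 2))
    if (totals == 0).any():
        raise FormatError("footprint with zero total weight")
    ax0 = np.arange(w.shape[1])
    ax1 = np.arange(w.shape[2])
    cx = (w.sum(axis=2) * ax0).sum(axis=1) / totals
    cy = (w.sum(axis=1) * ax1).sum(axis=1) / totals
    return cx, cy


def _open_store(path: str | Path) -> xr.Dataset:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"store {path} does not exist")
    if path.is_dir():
        return xr.open_zarr(path, consolidated=False)
    return xr.open_dataset(path)


def read_labeled_store(
    path: str | Path,
    trace_var: str = "C",
    footprint_var: str = "A",
    fps: float | None = None,
    interpolate_nans: bool = False,
    name: str | None = None,
) -> Recording:
    """Load a Minian-style labeled-array store into a :class:`Recording`."""
    ds = _open_store(path)
    if trace_var not in ds:
        raise FormatError(f"store has no trace variable {trace_var!r}")
    tr = ds[trace_var]
    if tr.ndim != 2:
        raise FormatError(f"trace variable {trace_var!r} must be 2-D, got {tr.ndim}-D")
    unit_dim = tr.dims[0]
    unit_ids = (
        np.asarray(ds[unit_dim].values, dtype=int)
        if unit_dim in ds.coords
        else np.arange(tr.shape[0])
    )
    traces = np.asarray(tr.values, dtype=float)
    if np.isnan(traces).any():
        if interpolate_nans:
            traces = _interpolate_short_gaps(traces, unit_ids)
        else:
            bad = unit_ids[np.isnan(traces).any(axis=1)]
            raise FormatError(f"NaN frames in units {bad.tolist()}; pass interpolate_nans=True for short gaps")
    if fps is None:
        fps = float(ds.attrs.get("fps", tr.attrs.get("fps", 20.0)))

    positions = None
    if footprint_var and footprint_var in ds:
        fp = ds[footprint_var]
        if fp.ndim != 3:
            raise FormatError(f"footprint variable {footprint_var!r} must be 3-D")
        cx, cy = _centroids(fp.values)
        positions = NeuronPositions(unit_ids=unit_ids.copy(), x=cx, y=cy)
    elif "x" in ds and "y" in ds:
        positions = NeuronPositions(
            unit_ids=unit_ids.copy(),
            x=np.asarray(ds["x"].values, float),
            y=np.asarray(ds["y"].values, float),
        )
    ds.close()
    return Recording(
        traces=TraceMatrix(intensities=traces, fps=fps, unit_ids=unit_ids),
        positions=positions,
        name=name or Path(path).stem,
    )


def write_labeled_store(rec: Recording, path: str | Path, trace_var: str = "C") -> Path:
    """Write a Recording as a zarr directory (or NetCDF when the path ends
    in ``.nc``) in the layout :func:`read_labeled_store` accepts."""
    path = Path(path)
    data = {trace_var: (("unit_id", "frame"), rec.traces.intensities)}
    if rec.positions is not None:
        data["x"] = (("unit_id",), rec.positions.x)
        data["y"] = (("unit_id",), rec.positions.y)
    ds = xr.Dataset(
        data,
        coords={"unit_id": rec.traces.unit_ids, "frame": np.arange(rec.traces.n_frames)},
        attrs={"fps": rec.fps, "name": rec.name},
    )
    if path.suffix == ".nc":
        ds.to_netcdf(path, engine="scipy")
    else:
        ds.to_zarr(path, mode="w", consolidated=False)
    return path


def read_table(
    traces_csv: str | Path,
    positions_csv: str | Path | None = None,
    fps: float = 20.0,
) -> Recording:
    """Read a traces CSV (rows = units, first column unit_id) and an
    optional positions CSV (columns unit_id, x, y)."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    try:
        df = pd.read_csv(traces_csv, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise FormatError(f"malformed traces CSV: {err}") from err
    if df.shape[1] < 3:
        raise FormatError("traces CSV needs a unit_id column plus at least 2 frames")
    if df.isna().any().any():
        raise FormatError("traces CSV contains missing values (ragged rows?)")
    unit_ids = df.iloc[:, 0].to_numpy(dtype=int)
    traces = df.iloc[:, 1:].to_numpy(dtype=float)

    positions = None
    if positions_csv is not None:
        pdf = pd.read_csv(positions_csv)
        for col in ("unit_id", "x", "y"):
            if col not in pdf.columns:
                raise FormatError(f"positions CSV missing column {col!r}")
        positions = NeuronPositions(
            unit_ids=pdf["unit_id"].to_numpy(dtype=int),
            x=pdf["x"].to_numpy(dtype=float),
            y=pdf["y"].to_numpy(dtype=float),
        )
    return Recording(
        traces=TraceMatrix(intensities=traces, fps=fps, unit_ids=unit_ids),
        positions=positions,
        name=Path(traces_csv).stem,
    )


def write_table(
    rec: Recording,
    traces_csv: str | Path,
    positions_csv: str | Path | None = None,
) -> None:
    """CSV mirror of :func:`read_table` (round trips bit-for-bit via repr)."""
    df = pd.DataFrame(rec.traces.intensities, columns=[f"f{i}" for i in range(rec.traces.n_frames)])
    df.insert(0, "unit_id", rec.traces.unit_ids)
    df.to_csv(traces_csv, index=False)
    if positions_csv is not None and rec.positions is not None:
        pd.DataFrame(
            {"unit_id": rec.positions.unit_ids, "x": rec.positions.x, "y": rec.positions.y}
        ).to_csv(positions_csv, index=False)


def write_report(tables: Mapping[str, pd.DataFrame], path: str | Path) -> Path:
    """One workbook with a sheet per table, plus CSV mirrors beside it.

    Sheet names are truncated to Excel's 31-character limit; the CSV mirror
    keeps the full table name (``<workbook-stem>_<table>.csv``).
    """
    if not tables:
        raise ValueError("nothing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for tab_name, df in tables.items():
            df.to_excel(xl, sheet_name=tab_name[:31], index=False)
    for tab_name, df in tables.items():
        df.to_csv(path.parent / f"{path.stem}_{tab_name}.csv", index=False)
    return path
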