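"""Tabular input/output for trace collections and analysis results.

The deposited single-cell tables use a *triplet-column* layout: each cell
occupies three neighbouring columns — average fluorescence, local
background, and background-subtracted signal — with an optional leading
time column; one worksheet (or file) per experimental replicate, each with
its own cell count.  The native interchange format here is CSV; the
spreadsheet dialect is supported read-only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "CellRecord",
    "TraceCollection",
    "read_tidy_table",
    "read_triplet_table",
    "write_triplet_table",
    "write_results",
    "read_results",
]


@dataclass
class CellRecord:
    cell_id: str
    raw: TimeSeries
    background: TimeSeries | None = None
    subtracted: TimeSeries | None = None


@dataclass
class TraceCollection:
    """A set of cells sharing a time grid, with experiment metadata."""

    cells: list[CellRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def dt_sample(self) -> float:
        return self.cells[0].raw.dt_sample

    def best_signal(self, cell: CellRecord) -> TimeSeries:
        """The background-subtracted channel when present, else raw."""
        return cell.subtracted if cell.subtracted is not None else cell.raw


def _frame_to_collection(df: pd.DataFrame, dt_sample: float,
                         source: str) -> TraceCollection:
    cols = list(df.columns)
    time_col = None
    first = str(cols[0]).strip().lower()
    if first in {"t", "time", "t_min", "time_min", "min"}:
        time_col = cols[0]
        cols = cols[1:]
    if len(cols) == 0 or len(cols) % 3 != 0:
        raise ValueError(
            f"{source}: expected a column count divisible by 3 "
            f"(plus an optional time column), found {len(cols)} data columns")
    if time_col is not None:
        t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(float)
    else:
        t = dt_sample * np.arange(len(df))
    cells = []
    for k in range(0, len(cols), 3):
        block = df[cols[k:k + 3]].apply(pd.to_numeric, errors="coerce")
        vals = block.to_numpy(float)
        # trim missing trailing values per cell
        present = np.isfinite(vals).any(axis=1)
        if not present.any():
            raise ValueError(f"{source}: column block {k // 3} is empty")
        last = int(np.nonzero(present)[0][-1]) + 1
        vals = vals[:last]
        tt = t[:last]
        finite_rows = np.isfinite(vals).all(axis=1)
        if not finite_rows.all():
            bad = int(np.nonzero(~finite_rows)[0][0])
            raise ValueError(
                f"{source}: non-numeric value in column block {k // 3} "
                f"(cell {k // 3}), row {bad}")
        cid = f"cell{k // 3:03d}"
        cells.append(CellRecord(
            cell_id=cid,
            raw=TimeSeries(tt, vals[:, 0], {"cell_id": cid}),
            background=TimeSeries(tt, vals[:, 1], {"cell_id": cid}),
            subtracted=TimeSeries(tt, vals[:, 2], {"cell_id": cid}),
        ))
    return TraceCollection(cells, meta={"source": source,
                                        "dt_sample": float(t[1] - t[0])})


def read_tidy_table(path) -> TraceCollection:
    """Read a tidy trace CSV (cell_id, t_min, intensity), one row per sample."""
    df = pd.read_csv(path)
    required = {"cell_id", "t_min", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: tidy trace tables need columns {sorted(required)}")
    cells = []
    for cid, g in df.groupby("cell_id", sort=False):
        ts = TimeSeries(g["t_min"].to_numpy(float),
                        g["intensity"].to_numpy(float), {"cell_id": str(cid)})
        cells.append(CellRecord(str(cid), ts))
    return TraceCollection(cells, meta={"source": str(path)})


def read_triplet_table(path, dialect: str = "auto", dt_sample: float = 2.0,
                       sheet=None) -> TraceCollection | dict:
    """Read a triplet-column trace table (CSV, or XLS/XLSX read-only).

    Tidy tables written by the ``simulate`` CLI (cell_id, t_min, intensity)
    are recognised and dispatched to :func:`read_tidy_table`.

    Parameters
    ----------
    path : str or Path
    dialect : {'auto', 'csv', 'excel'}
    dt_sample : float
        Sampling interval (min) used to synthesise the time grid when no
        time column is present.
    sheet : str or int, optional
        For spreadsheets: a single worksheet to read.  When omitted, every
        worksheet (replicate) is read and a dict mapping sheet name to
        :class:`TraceCollection` is returned; sheets may have different
        cell counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "excel" if path.suffix.lower() in {".xls", ".xlsx"} else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, nrows=1)
        if {"cell_id", "t_min", "intensity"} <= set(df.columns):
            return read_tidy_table(path)
        df = pd.read_csv(path)
        return _frame_to_collection(df, dt_sample, str(path))
    if dialect == "excel":
        if sheet is not None:
            df = pd.read_excel(path, sheet_name=sheet)
            return _frame_to_collection(df, dt_sample, f"{path}:{sheet}")
        frames = pd.read_excel(path, sheet_name=None)
        return {name: _frame_to_collection(df, dt_sample, f"{path}:{name}")
                for name, df in frames.items()}
    raise ValueError(f"unknown dialect {dialect!r}")


def write_triplet_table(collection: TraceCollection, path) -> Path:
    """Write a collection in the triplet-column CSV dialect (with time column)."""
    path = Path(path)
    data = {"time_min": collection.cells[0].raw.t}
    for c in collection.cells:
        data[f"{c.cell_id}_raw"] = c.raw.v
        bg = c.background.v if c.background is not None else np.zeros(len(c.raw))
        sub = c.subtracted.v if c.subtracted is not None else c.raw.v - bg
        data[f"{c.cell_id}_background"] = bg
        data[f"{c.cell_id}_subtracted"] = sub
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    return path


def _provenance(meta: dict | None) -> dict:
    from . import __version__

    base = {"software_version": __version__}
    if meta:
        for key in ("params_hash", "seed"):
            if key in meta:
                base[key] = meta[key]
    return base


def write_results(cycles_table: pd.DataFrame, quality_table: pd.DataFrame,
                  out_dir, meta: dict | None = None) -> dict:
    """Write tidy cycle and quality CSVs with provenance columns.

    ``cycles_table`` has one row per cycle, ``quality_table`` one row per
    cell; both may be empty (header-only files are still written).  Numeric
    formatting is locale-independent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(meta)
    paths = {}
    for name, table in (("cycles", cycles_table), ("quality", quality_table)):
        table = table.copy()
        for key, val in prov.items():
            table[key] = val if len(table) else pd.Series(dtype=object)
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    return paths


def read_results(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two CSVs written by :func:`write_results`."""
    out_dir = Path(out_dir)
    return (pd.read_csv(out_dir / "cycles.csv"),
            pd.read_csv(out_dir / "quality.csv"))
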