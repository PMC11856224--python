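"""Climate-grid projection of a fitted temperature response.

A fitted thermal performance curve is applied cell-by-cell to gridded
monthly minimum/maximum temperature layers (ESRI ASCII ``.asc`` or flat
binary ``.flt``/``.hdr``), the monthly responses are averaged over a growing
season, and the resulting percent-mortality surface is classified into
performance bands (low / moderate / high / very high).

Grids are stored north-up (row 0 = northernmost latitude row) with NaN
marking nodata internally; the on-disk sentinel (default −9999) is applied
on read/write.  Nodata propagates through all arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .thermal_models import ThermalModelParams, eval_thermal

__all__ = [
    "ClimateGrid",
    "MonthlyStack",
    "PerformanceMap",
    "GridParseError",
    "GridDimensionError",
    "UnsupportedDialectError",
    "read_grid",
    "write_ascii_grid",
    "write_flt_grid",
    "read_monthly_stack",
    "project_response",
    "classify_performance",
    "hours_in_ranges",
    "daily_hours_in_ranges",
    "DEFAULT_MONTHS",
    "DEFAULT_EDGES",
    "DEFAULT_LABELS",
    "DEFAULT_BAND_EDGES_C",
]

DEFAULT_NODATA = -9999.0
#: Soybean growing season (October through March).
DEFAULT_MONTHS: tuple[int, ...] = (10, 11, 12, 1, 2, 3)
#: Percent-mortality class boundaries and band names.
DEFAULT_EDGES: tuple[float, ...] = (10.0, 25.0, 60.0)
DEFAULT_LABELS: tuple[str, ...] = ("low", "moderate", "high", "very high")
#: Temperature band edges (°C) for hourly exposure summaries.
DEFAULT_BAND_EDGES_C: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0)


class GridParseError(ValueError):
    """Malformed raster header or body."""


class GridDimensionError(ValueError):
    """Row/column count does not match the declared geometry."""


class UnsupportedDialectError(ValueError):
    """A raster dialect this reader deliberately does not handle."""


@dataclass(frozen=True)
class ClimateGrid:
    """Georeferenced raster: rows = latitude (north at row 0), cols = longitude.

    ``values`` holds float data with NaN at nodata cells; ``nodata`` is the
    on-disk sentinel.  Corner coordinates and cellsize are in degrees.
    """

    values: np.ndarray
    cellsize: float
    xllcorner: float
    yllcorner: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise GridDimensionError(f"grid must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is valid (not nodata)."""
        return ~np.isnan(self.values)

    def same_geometry(self, other: "ClimateGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cellsize - other.cellsize) <= tol
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
        )


_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_ascii(path: Path) -> ClimateGrid:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_KEYS:
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridParseError(f"unparseable header value for {key!r}: {parts[1]!r}") from exc
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridParseError(f"missing required header key {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    rows = []
    for i, line in enumerate(lines[body_start:]):
        if not line.strip():
            continue
        try:
            row = np.array(line.split(), dtype=float)
        except ValueError as exc:
            raise GridParseError(f"unparseable value in data row {i}") from exc
        if row.size != ncols:
            raise GridDimensionError(
                f"data row {i} has {row.size} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridDimensionError(f"found {len(rows)} data rows, expected nrows={nrows}")
    values = np.vstack(rows)
    values[values == nodata] = np.nan
    return ClimateGrid(
        values=values, cellsize=header["cellsize"],
        xllcorner=header["xllcorner"], yllcorner=header["yllcorner"], nodata=nodata,
    )


def _read_flt(path: Path) -> ClimateGrid:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise GridParseError(f"missing sidecar header {hdr_path}")
    header: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        parts = line.split()
        if len(parts) >= 2:
            header[parts[0].lower()] = parts[1]
    byteorder = header.get("byteorder", "LSBFIRST").upper()
    if byteorder != "LSBFIRST":
        raise UnsupportedDialectError(
            f"flat-binary byteorder {byteorder!r} not supported; only little-endian "
            "(LSBFIRST) layers are read"
        )
    try:
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        xll = float(header["xllcorner"])
        yll = float(header["yllcorner"])
        cellsize = float(header["cellsize"])
    except KeyError as exc:
        raise GridParseError(f"missing required header key {exc.args[0]!r}") from exc
    nodata = float(header.get("nodata_value", DEFAULT_NODATA))
    raw = np.fromfile(path, dtype="<f4")
    if raw.size != nrows * ncols:
        raise GridDimensionError(
            f"flt payload has {raw.size} floats, expected {nrows}x{ncols}"
        )
    values = raw.astype(float).reshape(nrows, ncols)
    values[values == np.float64(np.float32(nodata))] = np.nan
    values[values == nodata] = np.nan
    return ClimateGrid(values=values, cellsize=cellsize, xllcorner=xll,
                       yllcorner=yll, nodata=nodata)


def read_grid(path: str | Path, format: str | None = None) -> ClimateGrid:
    """Read an ESRI ASCII (.asc) or flat binary (.flt + .hdr) raster.

    ``format`` may be ``"ascii_grid"`` or ``"flat_binary"``; by default it is
    inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "flat_binary" if path.suffix.lower() == ".flt" else "ascii_grid"
    if format == "ascii_grid":
        return _read_ascii(path)
    if format == "flat_binary":
        return _read_flt(path)
    raise ValueError(f"unknown format {format!r}")


def write_ascii_grid(grid: ClimateGrid, path: str | Path) -> None:
    """Write the ESRI ASCII dialect: fixed header key order, 6 significant
    digits, '.' decimal separator, nodata cells as the sentinel."""
    path = Path(path)
    out = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.xllcorner:.6g}",
        f"yllcorner {grid.yllcorner:.6g}",
        f"cellsize {grid.cellsize:.6g}",
        f"NODATA_value {grid.nodata:.6g}",
    ]
    filled = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    for row in filled:
        out.append(" ".join(f"{v:.6g}" for v in row))
    path.write_text("\n".join(out) + "\n")


def write_flt_grid(grid: ClimateGrid, path: str | Path) -> None:
    """Write little-endian float32 flat binary plus its .hdr sidecar."""
    path = Path(path)
    filled = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    filled.astype("<f4").tofile(path)
    hdr = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.xllcorner:.6g}",
        f"yllcorner {grid.yllcorner:.6g}",
        f"cellsize {grid.cellsize:.6g}",
        f"NODATA_value {grid.nodata:.6g}",
        "BYTEORDER LSBFIRST",
    ]
    path.with_suffix(".hdr").write_text("\n".join(hdr) + "\n")


@dataclass(frozen=True)
class MonthlyStack:
    """Twelve monthly minimum- and maximum-temperature layers (°C), keyed 1-12."""

    tmin: dict[int, ClimateGrid]
    tmax: dict[int, ClimateGrid]

    def __post_init__(self) -> None:
        if set(self.tmin) != set(range(1, 13)) or set(self.tmax) != set(range(1, 13)):
            raise ValueError("stack requires layers for every month 1..12")
        ref = self.tmin[1]
        for m in range(1, 13):
            for layer in (self.tmin[m], self.tmax[m]):
                if not ref.same_geometry(layer):
                    raise GridDimensionError(f"layer geometry mismatch in month {m}")
            both = self.tmin[m].mask() & self.tmax[m].mask()
            if np.any(self.tmin[m].values[both] > self.tmax[m].values[both] + 1e-9):
                raise ValueError(f"tmin exceeds tmax in month {m}")

    @property
    def geometry(self) -> ClimateGrid:
        return self.tmin[1]


def read_monthly_stack(tmin_dir: str | Path, tmax_dir: str | Path,
                       pattern: str = "{month:02d}") -> MonthlyStack:
    """Load 12 tmin and 12 tmax layers from two directories.

    Files are matched by substituting the month into ``pattern`` and
    accepting either ``.asc`` or ``.flt`` extensions.
    """
    def find(d: Path, month: int) -> ClimateGrid:
        stem = pattern.format(month=month)
        for ext in (".asc", ".flt"):
            cands = sorted(d.glob(f"*{stem}{ext}"))
            if cands:
                return read_grid(cands[0])
        raise FileNotFoundError(f"no layer matching *{stem}.asc/.flt in {d}")

    tmin_dir, tmax_dir = Path(tmin_dir), Path(tmax_dir)
    return MonthlyStack(
        tmin={m: find(tmin_dir, m) for m in range(1, 13)},
        tmax={m: find(tmax_dir, m) for m in range(1, 13)},
    )


@dataclass(frozen=True)
class PerformanceMap:
    """Predicted percent mortality per cell, optionally classified into bands."""

    mortality: ClimateGrid
    classes: np.ndarray | None = None  # int band index, -1 at nodata
    class_edges: tuple[float, ...] = ()
    class_labels: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)


_POLICIES = ("midpoint", "min", "max", "mean_of_two")


def project_response(
    stack: MonthlyStack,
    params: ThermalModelParams,
    months: Iterable[int] = DEFAULT_MONTHS,
    policy: str = "midpoint",
) -> PerformanceMap:
    """Apply a fitted temperature response to every grid cell.

    For each selected month the cell's evaluation temperature is chosen by
    ``policy`` (default the min/max midpoint), the model is evaluated, and
    the monthly responses are averaged.  The mean response is expressed as
    percent mortality capped at 100; nodata propagates.
    """
    months = tuple(months)
    if not months:
        raise ValueError("months must be non-empty")
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}, got {policy!r}")
    acc = np.zeros_like(stack.geometry.values)
    for m in months:
        tmin = stack.tmin[m].values
        tmax = stack.tmax[m].values
        if policy == "midpoint":
            resp = eval_thermal((tmin + tmax) / 2.0, params)
        elif policy == "min":
            resp = eval_thermal(tmin, params) + 0.0 * tmax  # propagate tmax nodata
        elif policy == "max":
            resp = eval_thermal(tmax, params) + 0.0 * tmin
        else:
            resp = (eval_thermal(tmin, params) + eval_thermal(tmax, params)) / 2.0
        acc = acc + resp
    mean_resp = acc / len(months)
    percent = np.minimum(mean_resp * 100.0, 100.0)
    geom = stack.geometry
    grid = ClimateGrid(values=percent, cellsize=geom.cellsize,
                       xllcorner=geom.xllcorner, yllcorner=geom.yllcorner,
                       nodata=geom.nodata)
    meta = {"model": params.to_dict(), "policy": policy, "months": list(months)}
    return PerformanceMap(mortality=grid, metadata=meta)


def classify_performance(
    perf: PerformanceMap,
    edges: Sequence[float] = DEFAULT_EDGES,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> PerformanceMap:
    """Partition percent mortality into half-open bands [lo, hi).

    With the default edges (10, 25, 60): low = [0, 10), moderate = [10, 25),
    high = [25, 60), very high = [60, 100].  A cell exactly on an edge falls
    in the band above it.
    """
    edges = tuple(float(e) for e in edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError(f"edges must be strictly increasing, got {edges}")
    if any(not 0.0 < e < 100.0 for e in edges):
        raise ValueError(f"edges must lie strictly inside (0, 100), got {edges}")
    labels = tuple(labels)
    if len(labels) != len(edges) + 1:
        raise ValueError(f"need {len(edges) + 1} labels for {len(edges)} edges")
    vals = perf.mortality.values
    classes = np.searchsorted(edges, vals, side="right").astype(int)
    classes[np.isnan(vals)] = -1
    meta = dict(perf.metadata, edges=list(edges), labels=list(labels))
    return PerformanceMap(
        mortality=perf.mortality, classes=classes,
        class_edges=edges, class_labels=labels, metadata=meta,
    )


# --- hourly exposure summaries ----------------------------------------------

def _band_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"<={edges[0]:g}"]
    labels += [f"({lo:g},{hi:g}]" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]:g}")
    return labels


def daily_hours_in_ranges(
    series: pd.Series, edges: Sequence[float] = DEFAULT_BAND_EDGES_C
) -> pd.DataFrame:
    """Hours per calendar day spent in each temperature band.

    Bands are contiguous half-open intervals (−∞, e1], (e1, e2], …, (ek, ∞),
    so a reading exactly on an edge counts in the band below-or-equal.  Rows
    are days, columns band labels; per-day counts sum to the number of valid
    hourly readings that day.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by timestamps")
    series = series.dropna()
    if series.empty:
        raise ValueError("empty temperature series")
    edges = tuple(float(e) for e in edges)
    band = np.searchsorted(edges, series.to_numpy(), side="left")
    labels = _band_labels(edges)
    df = pd.DataFrame({"date": series.index.normalize(), "band": band})
    counts = (
        df.groupby(["date", "band"]).size().unstack(fill_value=0)
        .reindex(columns=range(len(labels)), fill_value=0)
    )
    counts.columns = labels
    return counts


def hours_in_ranges(
    series: pd.Series, edges: Sequence[float] = DEFAULT_BAND_EDGES_C
) -> pd.DataFrame:
    """Per-month mean hours/day in each temperature band (rows = month 1-12)."""
    daily = daily_hours_in_ranges(series, edges)
    monthly = daily.groupby(daily.index.month).mean()
    monthly.index.name = "month"
    return monthly
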