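"""Readers and writers for the external file formats.

Three formats are handled:

* **Fix CSV** — one GPS position per row, Movebank-style column names by
  default (``individual-local-identifier``, ``timestamp``, ``location-long``,
  ``location-lat``); projected ``x``/``y`` columns in meters are accepted as
  an alternative to lon/lat.  Timestamps are ISO-8601 UTC.
* **Accelerometer CSV** — one tri-axial sample per row with the burst start
  time and the within-burst offset; nominally 20 Hz for 10 s every 3 min.
* **Covariate raster** — ESRI ASCII grid (text ``.asc``), one layer per file.

Everything downstream operates on the validated pandas tables returned here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .projection import LocalTransverseMercator

logger = logging.getLogger("stepflow")

NOMINAL_BURST_SAMPLES = 200   # 20 Hz x 10 s


class FormatError(ValueError):
    """Input file does not match the documented format."""


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

def read_fixes(path, config: Optional[RunConfig] = None,
               projection: Optional[LocalTransverseMercator] = None) -> pd.DataFrame:
    """Read a fix CSV into a table sorted by (individual, timestamp).

    Duplicate (individual, timestamp) rows are collapsed to the first
    occurrence with a logged warning count.  If the file carries lon/lat they
    are projected to planar meters; a projection centred on the data centroid
    is built unless one is supplied (or fixed in the config).

    Returns a DataFrame with columns ``individual_id, timestamp, x, y`` (plus
    ``lon, lat`` when present in the source).
    """
    config = config or RunConfig()
    cols = config.fix_columns
    raw = pd.read_csv(path)

    def need(key):
        name = cols[key]
        if name not in raw.columns:
            raise FormatError(f"missing required column {name!r} in {path}")
        return name

    out = pd.DataFrame({"individual_id": raw[need("individual")].astype(str)})
    ts_col = need("timestamp")
    ts = pd.to_datetime(raw[ts_col], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw[ts_col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(
            f"unparseable timestamp {raw.loc[bad.idxmax(), ts_col]!r} "
            f"at line {line} of {path}")
    out["timestamp"] = ts

    has_xy = cols["x"] in raw.columns and cols["y"] in raw.columns
    has_ll = cols["lon"] in raw.columns and cols["lat"] in raw.columns
    if has_ll:
        lon = raw[cols["lon"]].astype(float)
        lat = raw[cols["lat"]].astype(float)
        if projection is None:
            if config.projection_lon0 is not None and config.projection_lat0 is not None:
                projection = LocalTransverseMercator(config.projection_lon0,
                                                    config.projection_lat0)
            else:
                projection = LocalTransverseMercator.for_centroid(lon, lat)
        x, y = projection.forward(lon, lat)
        out["lon"], out["lat"] = lon, lat
        out["x"], out["y"] = x, y
        out.attrs["projection"] = projection
    elif has_xy:
        out["x"] = raw[cols["x"]].astype(float)
        out["y"] = raw[cols["y"]].astype(float)
    else:
        raise FormatError(
            f"need either columns ({cols['lon']!r}, {cols['lat']!r}) or "
            f"({cols['x']!r}, {cols['y']!r}) in {path}")

    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise FormatError(f"non-finite coordinates in {path}")

    out = out.sort_values(["individual_id", "timestamp"], kind="stable")
    dup = out.duplicated(["individual_id", "timestamp"])
    n_dup = int(dup.sum())
    if n_dup:
        logger.warning("read_fixes: dropped %d duplicate (individual, timestamp) rows",
                       n_dup)
    out = out[~dup].reset_index(drop=True)
    out.attrs["n_duplicates_dropped"] = n_dup
    logger.info("read_fixes: %d fixes, %d individuals",
                len(out), out["individual_id"].nunique())
    return out


def write_fixes(df: pd.DataFrame, path, config: Optional[RunConfig] = None) -> None:
    """Write fixes back out with the configured (Movebank-style) headers."""
    cols = (config or RunConfig()).fix_columns
    out = pd.DataFrame({cols["individual"]: df["individual_id"]})
    out[cols["timestamp"]] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    if "lon" in df.columns:
        out[cols["lon"]] = df["lon"]
        out[cols["lat"]] = df["lat"]
    else:
        out[cols["x"]] = df["x"]
        out[cols["y"]] = df["y"]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Accelerometer bursts
# ---------------------------------------------------------------------------

ACC_COLUMNS = ["individual_id", "burst_start", "t_offset", "ax", "ay", "az"]


def read_acc(path) -> pd.DataFrame:
    """Read an accelerometer CSV; flag bursts with <50% of nominal samples.

    Returns a DataFrame with ``ACC_COLUMNS`` plus a per-row ``complete`` flag
    shared by all samples of a burst.
    """
    raw = pd.read_csv(path)
    missing = [c for c in ACC_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    out = raw[ACC_COLUMNS].copy()
    out["individual_id"] = out["individual_id"].astype(str)
    out["burst_start"] = pd.to_datetime(out["burst_start"], utc=True, format="ISO8601")
    for c in ("t_offset", "ax", "ay", "az"):
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = vals.isna() & out[c].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"non-numeric value in column {c!r} at line {line} of {path}")
        out[c] = vals
    out = out.sort_values(["individual_id", "burst_start", "t_offset"],
                          kind="stable").reset_index(drop=True)
    sizes = out.groupby(["individual_id", "burst_start"], sort=False)["ax"].transform("size")
    out["complete"] = sizes >= NOMINAL_BURST_SAMPLES // 2
    n_inc = int((~out["complete"]).sum())
    if n_inc:
        logger.warning("read_acc: %d samples in incomplete bursts", n_inc)
    return out


# ---------------------------------------------------------------------------
# Covariate rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass
class CovariateGrid:
    """Single-layer raster: values[0, 0] is the north-west (top-left) cell.

    ``x0, y0`` are the coordinates of the lower-left corner; cell membership
    is half-open in both axes, ``[x0 + i*cell, x0 + (i+1)*cell)``, so every
    point inside the extent belongs to exactly one cell.
    """

    layer_name: str
    x0: float
    y0: float
    cell_size: float
    values: np.ndarray              # (nrows, ncols), float
    nodata: float = -9999.0
    categories: dict = field(default_factory=dict)   # code -> label, optional

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise FormatError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_index(self, x, y):
        """(row, col) indices for points; -1 marks out-of-extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell_size).astype(int)
        row = self.nrows - 1 - row_from_bottom
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return np.where(ok, row, -1), np.where(ok, col, -1)

    def value_at(self, x, y):
        """Containing-cell lookup; out-of-extent and nodata cells yield NaN."""
        row, col = self.cell_index(x, y)
        scalar = np.ndim(row) == 0
        row, col = np.atleast_1d(row), np.atleast_1d(col)
        vals = np.full(row.shape, np.nan)
        ok = row >= 0
        vals[ok] = self.values[row[ok], col[ok]]
        vals[vals == self.nodata] = np.nan
        return float(vals[0]) if scalar else vals


def read_grid(path, layer_name: Optional[str] = None) -> CovariateGrid:
    """Read an ESRI ASCII grid (.asc). Other raster formats are rejected."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        raise FormatError(
            "GeoTIFF input is not supported; convert to ESRI ASCII grid (.asc)")
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"ASCII grid {path} missing header field {req!r}")
    values = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    name = layer_name or path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return CovariateGrid(
        layer_name=name,
        x0=header["xllcorner"], y0=header["yllcorner"],
        cell_size=header["cellsize"], values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_grid(grid: CovariateGrid, path) -> None:
    """Write a grid as ESRI ASCII with full float precision (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(grid.x0)!r}\n")
        fh.write(f"yllcorner {float(grid.y0)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in np.where(np.isnan(grid.values), grid.nodata, grid.values):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
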