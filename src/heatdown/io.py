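"""Raster and table I/O.

Two raster containers are supported, chosen by file extension:

* **GeoTIFF** (``.tif``/``.tiff``) — single-band, written with the standard
  GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint) so the files
  open in any GIS.  Scaled-integer land-surface-temperature rasters (raw
  Kelvin x 50 with a fill value, MYD11A2-style) are written as uint16.
* **NetCDF** (``.nc``) — CF-style, a 2-D variable with 1-D ``lat``/``lon``
  center-coordinate variables, NetCDF3 classic on the wire.

Station observation tables travel as CSV with the header
``station_id,lon,lat,date,obs_tmax_c`` and ISO-8601 dates.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .grids import Field2D, GridSpec

__all__ = [
    "read_raster",
    "write_raster",
    "read_cube",
    "write_cube",
    "read_stations",
    "write_stations",
]

# GeoTIFF georeferencing tags (GeoTIFF spec, always in this tag order)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922

STATION_COLUMNS = ["station_id", "lon", "lat", "date", "obs_tmax_c"]


def _is_netcdf(path: os.PathLike | str) -> bool:
    suffix = Path(path).suffix.lower()
    if suffix in {".nc", ".nc4", ".cdf"}:
        return True
    if suffix in {".tif", ".tiff"}:
        return False
    raise ValueError(f"cannot infer raster format from extension: {path!r}")


def write_raster(
    field: Field2D,
    path: os.PathLike | str,
    *,
    name: str = "temperature",
    dtype: str | None = None,
    fill: float | None = None,
) -> None:
    """Write a single-band raster; format chosen by extension.

    Invalid pixels are written as NaN for float data or as ``fill`` for
    integer data (``fill`` is then required).
    """
    path = Path(path)
    if dtype is not None and np.issubdtype(np.dtype(dtype), np.integer):
        if fill is None:
            raise ValueError("integer rasters require an explicit fill value")
        data = np.where(field.valid, field.values, fill).astype(dtype)
    else:
        data = field.masked().astype(dtype or "float64")

    if _is_netcdf(path):
        da = xr.DataArray(
            data,
            dims=("lat", "lon"),
            coords={
                "lat": ("lat", field.spec.lat_centers(), {"units": "degrees_north"}),
                "lon": ("lon", field.spec.lon_centers(), {"units": "degrees_east"}),
            },
            name=name,
        )
        if fill is not None:
            da.attrs["_FillValue_declared"] = float(fill)
        da.to_dataset().to_netcdf(path, engine="scipy")
    else:
        spec = field.spec
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.dx, spec.dy, 0.0)),
            (
                _TAG_MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, spec.west, spec.north, 0.0),
            ),
        ]
        tifffile.imwrite(path, data, extratags=extratags)


def read_raster(
    path: os.PathLike | str,
    *,
    fill: float | None = None,
) -> Field2D:
    """Read a single-band GeoTIFF or NetCDF raster into a :class:`Field2D`.

    ``fill`` marks pixels equal to that raw value as invalid — the default
    for scaled-integer LST rasters is ``0`` (0 K is physically impossible),
    applied automatically when the stored dtype is integer.  Float rasters
    treat NaN as invalid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if _is_netcdf(path):
        with xr.open_dataset(path, engine="scipy") as ds:
            data_vars = [v for v in ds.data_vars if ds[v].ndim == 2]
            if not data_vars:
                raise ValueError(f"no 2-D variable found in {path}")
            da = ds[data_vars[0]].load()
            if "lat" not in da.coords or "lon" not in da.coords:
                raise ValueError(f"missing lat/lon coordinates in {path}")
            lat = np.asarray(da["lat"].values, dtype=float)
            lon = np.asarray(da["lon"].values, dtype=float)
            values = np.asarray(da.values)
        dy = float(lat[0] - lat[1]) if lat.size > 1 else _single_step(lat)
        dx = float(lon[1] - lon[0]) if lon.size > 1 else _single_step(lon)
        if dy <= 0 or dx <= 0:
            raise ValueError("latitude must decrease and longitude increase")
        spec = GridSpec(
            west=float(lon[0] - dx / 2),
            north=float(lat[0] + dy / 2),
            dx=dx,
            dy=dy,
            nrows=lat.size,
            ncols=lon.size,
        )
    else:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            tags = page.tags
            if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
                raise ValueError(f"missing GeoTIFF georeferencing tags in {path}")
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
            tie = tags[_TAG_MODEL_TIEPOINT].value
            i, j, _, x, y, _ = tie[:6]
            values = page.asarray()
        spec = GridSpec(
            west=float(x - i * sx),
            north=float(y + j * sy),
            dx=float(sx),
            dy=float(sy),
            nrows=values.shape[0],
            ncols=values.shape[1],
        )

    if values.ndim != 2:
        raise ValueError(f"expected a single-band 2-D raster, got {values.shape}")

    if np.issubdtype(values.dtype, np.integer) and fill is None:
        fill = 0
    fvalues = values.astype(float)
    valid = np.isfinite(fvalues)
    if fill is not None:
        valid &= values != fill
        fvalues = np.where(valid, fvalues, np.nan)
    return Field2D(spec=spec, values=fvalues, valid=valid)


def _single_step(coord: np.ndarray) -> float:
    raise ValueError("cannot infer pixel size from a single-pixel axis")


def write_cube(cube, path: os.PathLike | str, *, name: str = "t2m") -> None:
    """Write an hourly temperature cube as CF-style NetCDF (time, lat, lon)."""
    da = xr.DataArray(
        cube.values,
        dims=("time", "lat", "lon"),
        coords={
            "time": ("time", cube.times),
            "lat": ("lat", cube.spec.lat_centers(), {"units": "degrees_north"}),
            "lon": ("lon", cube.spec.lon_centers(), {"units": "degrees_east"}),
        },
        name=name,
        attrs={"units": "degC", "long_name": "2 m air temperature"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_cube(path: os.PathLike | str):
    """Read an hourly temperature cube written by :func:`write_cube`."""
    from .temporal import HourlySeriesCube

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [v for v in ds.data_vars if ds[v].ndim == 3]
        if not names:
            raise ValueError(f"no 3-D variable found in {path}")
        da = ds[names[0]].load()
        lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        times = np.asarray(da["time"].values)
        values = np.asarray(da.values, dtype=float)
    dy = float(lat[0] - lat[1])
    dx = float(lon[1] - lon[0])
    spec = GridSpec(
        west=float(lon[0] - dx / 2),
        north=float(lat[0] + dy / 2),
        dx=dx,
        dy=dy,
        nrows=lat.size,
        ncols=lon.size,
    )
    return HourlySeriesCube(spec=spec, times=times, values=values)


def write_stations(table: pd.DataFrame, path: os.PathLike | str) -> None:
    """Write a station observation table as CSV (ISO-8601 dates)."""
    df = table.loc[:, STATION_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_stations(path: os.PathLike | str) -> pd.DataFrame:
    """Read a station observation table.

    Enforces the invariants: unique (station_id, date) pairs, finite
    coordinates.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(subset=["station_id", "date"]).any():
        raise ValueError("duplicate (station_id, date) rows in station table")
    if not np.isfinite(df[["lon", "lat"]].to_numpy()).all():
        raise ValueError("non-finite station coordinates")
    return df
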