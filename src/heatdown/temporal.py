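"""Daily temperature extrema from hourly forcing, in local standard time.

Coarse reanalysis forcing comes as hourly 2 m air temperature with UTC
timestamps.  The daily maximum that the downscaling equation consumes is the
maximum over the 24 hourly values of the pixel's *local standard* calendar
day, where the local offset is derived from longitude (``round(lon / 15)``
hours, ties away from zero) rather than civil time zones — deterministic and
dependency-free, and within an hour of civil standard time everywhere the
method applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Field2D, GridSpec

__all__ = [
    "HourlySeriesCube",
    "DailyExtrema",
    "local_utc_offset",
    "daily_extrema",
]


def local_utc_offset(lon):
    """Whole-hour standard-time offset from UTC for a longitude.

    ``round(lon / 15)`` with ties rounded away from zero, so -112.5 deg gives
    -8, +112.5 gives +8.
    """
    lon = np.asarray(lon, dtype=float)
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude outside [-180, 180]")
    x = lon / 15.0
    out = np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int64)
    return out if out.ndim else int(out)


@dataclass
class HourlySeriesCube:
    """Hourly 2 m air temperature on a coarse grid.

    ``times`` are UTC instants on a strict uniform hourly step; ``values``
    has shape ``(len(times), nrows, ncols)`` in degrees Celsius, NaN where
    missing.
    """

    spec: GridSpec
    times: np.ndarray  # datetime64[ns] or [h], strictly increasing hourly
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, *self.spec.shape):
            raise ValueError("cube shape does not match (ntimes, nrows, ncols)")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if not np.all(steps == np.timedelta64(1, "h")):
                raise ValueError("timestamps must be a uniform hourly sequence")


@dataclass
class DailyExtrema:
    """Per-pixel daily max (and min) air temperature for one local day.

    ``tmax`` is the T_L of the downscaling equation when computed on the
    coarse forcing grid.
    """

    spec: GridSpec
    date: np.datetime64
    tmax: Field2D
    tmin: Field2D | None = None


def daily_extrema(
    cube: HourlySeriesCube, date, *, with_min: bool = True
) -> DailyExtrema:
    """Max (and min) over the 24 local-standard-time hours of ``date``.

    Each pixel's local day is determined by its column longitude.  A pixel
    with any missing hourly value in its window is flagged invalid — a
    partial maximum would carry a silent cold bias.  If the cube does not
    cover some pixel's window at all, an error names the missing span.
    """
    date64 = np.datetime64(np.datetime_as_string(np.datetime64(date, "D")), "ns")
    lons = cube.spec.lon_centers()
    offsets = np.asarray(local_utc_offset(lons))
    t0 = cube.times[0]

    nr, nc = cube.spec.shape
    tmax = np.full((nr, nc), np.nan)
    tmin = np.full((nr, nc), np.nan)
    hour = np.timedelta64(1, "h")

    for off in np.unique(offsets):
        cols = offsets == off
        # local time = UTC + off hours; local day [00, 24) maps to
        # UTC [date - off, date - off + 24)
        start_utc = date64 - int(off) * hour
        i0 = int((start_utc - t0) / hour)
        if i0 < 0 or i0 + 24 > cube.times.size:
            raise ValueError(
                f"hourly cube does not cover local day {np.datetime_as_string(date64, unit='D')} "
                f"(UTC span {np.datetime_as_string(start_utc, unit='h')} +24h) "
                f"for longitudes with offset {int(off):+d}h"
            )
        if cube.times[i0] != start_utc:
            raise ValueError("cube timestamps are not aligned to whole hours")
        block = cube.values[i0 : i0 + 24][:, :, cols]
        complete = np.isfinite(block).all(axis=0)
        bmax = np.max(block, axis=0)
        bmin = np.min(block, axis=0)
        tmax[:, cols] = np.where(complete, bmax, np.nan)
        tmin[:, cols] = np.where(complete, bmin, np.nan)

    out_max = Field2D(cube.spec, tmax)
    out_min = Field2D(cube.spec, tmin) if with_min else None
    return DailyExtrema(spec=cube.spec, date=date64, tmax=out_max, tmin=out_min)
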