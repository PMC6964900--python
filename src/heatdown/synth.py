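"""Synthetic co-registered worlds for exercising the full pipeline.

The generator emulates the structure the downscaling method assumes:

* a *stable* fine-scale thermal anomaly pattern ``a`` (urban warm bumps,
  optionally a cool water margin), re-centered to zero mean within every
  coarse cell so the synthetic world satisfies the method's conservation
  premise exactly;
* coarse daily weather — a smooth regional gradient plus seeded day-to-day
  variation — delivered as an hourly cube whose sinusoidal diurnal cycle
  peaks at 14:00 local standard time, near the early-afternoon satellite
  overpass;
* fine-scale "truth" air temperature built as the upsampled coarse daily
  peak plus ``r_true * a``, encoding the assumption that air-temperature
  patterns mimic LST patterns at a reduced amplitude (``r_true`` defaults
  to 0.5);
* LST scenes = base LST + ``a`` + noise, degraded by blocky cloud masks
  (random rectangles, not i.i.d. pixels, to stress per-cell fallbacks) and
  occasional cold-contaminated pixels that the upper-half composite must
  reject.

All randomness flows from the single recipe seed: identical recipes give
bit-identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .grids import CellMap, GridSpec, build_cell_map
from .composite import SceneStack
from .temporal import HourlySeriesCube, local_utc_offset

__all__ = [
    "UrbanCenter",
    "SceneRecipe",
    "SyntheticTruth",
    "default_dates",
    "make_truth",
    "make_lst_stack",
    "make_stations",
]


def _default_fine() -> GridSpec:
    return GridSpec(west=-91.0, north=39.25, dx=0.125 / 12, dy=0.125 / 12,
                    nrows=96, ncols=96)


def _default_coarse() -> GridSpec:
    return GridSpec(west=-91.0, north=39.25, dx=0.125, dy=0.125,
                    nrows=8, ncols=8)


def default_dates() -> pd.DatetimeIndex:
    """The evaluation calendar: June-August of 2009, 2010 and 2011."""
    parts = [
        pd.date_range(f"{y}-06-01", f"{y}-08-31", freq="D")
        for y in (2009, 2010, 2011)
    ]
    return parts[0].append(parts[1:])


@dataclass(frozen=True)
class UrbanCenter:
    """A Gaussian warm bump in the anomaly field (fine-pixel coordinates)."""

    row: int
    col: int
    amplitude_c: float = 3.0
    radius_px: float = 6.0


@dataclass
class SceneRecipe:
    """Everything needed to generate one synthetic world.

    Defaults describe a 1 degree x 1 degree mid-latitude domain with a 12:1
    nesting (8 x 8 coarse cells of 1/8 degree over a 96 x 96 fine grid),
    two urban heat islands, warm-season weather around 30 C with an 8 C
    diurnal range peaking at 14:00 local, a 19-scene season of LST
    composites with 30% blocky cloud cover and 0.5 C scene noise, and an
    air/LST anomaly coupling of 0.5.
    """

    fine: GridSpec = dfield(default_factory=_default_fine)
    coarse: GridSpec = dfield(default_factory=_default_coarse)
    urban_centers: list[UrbanCenter] = dfield(
        default_factory=lambda: [UrbanCenter(30, 30, 3.0, 6.0),
                                 UrbanCenter(64, 70, 2.0, 5.0)]
    )
    coast_col: int | None = None  # fine columns >= this are "water"
    water_offset_c: float = -5.0
    base_mean_c: float = 30.0  # domain-mean daily maximum
    base_amplitude_c: float = 8.0  # peak-to-trough diurnal range
    peak_hour: int = 14  # local standard time of the daily max
    gradient_c: float = 2.0  # west-east regional gradient amplitude
    weather_sd_c: float = 3.0  # day-to-day variation of the daily max
    r_true: float = 0.5  # air-anomaly / LST-anomaly coupling
    base_lst_c: float = 45.0  # clear-sky scene background LST
    noise_sd_c: float = 0.5  # per-scene LST noise
    cloud_fraction: float = 0.3  # area fraction removed per scene
    contam_fraction: float = 0.01  # cold-contaminated pixel fraction
    contam_offset_c: float = -15.0
    obs_noise_sd_c: float = 0.5  # station observation noise
    n_scenes: int = 19  # May-September of 8-day composites
    dates: pd.DatetimeIndex = dfield(default_factory=default_dates)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cloud_fraction < 1):
            raise ValueError("cloud_fraction must be in [0, 1)")
        if self.r_true <= 0:
            raise ValueError("r_true must be positive")
        if self.n_scenes < 1:
            raise ValueError("need at least one scene")

    def cell_map(self) -> CellMap:
        return build_cell_map(self.fine, self.coarse)


@dataclass
class SyntheticTruth:
    """The generated world: anomaly, daily truth, and the hourly forcing."""

    recipe: SceneRecipe
    a: np.ndarray  # (nr_f, nc_f) zero-mean-per-cell anomaly, deg C
    dates: pd.DatetimeIndex
    coarse_tmax: np.ndarray  # (n_days, nr_c, nc_c) deg C
    fine_tmax: np.ndarray  # (n_days, nr_f, nc_f) deg C
    cube: HourlySeriesCube
    cmap: CellMap


def _anomaly_raw(recipe: SceneRecipe) -> np.ndarray:
    nr, nc = recipe.fine.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    a = np.zeros((nr, nc))
    for u in recipe.urban_centers:
        d2 = (rr - u.row) ** 2 + (cc - u.col) ** 2
        a += u.amplitude_c * np.exp(-d2 / (2.0 * u.radius_px**2))
    if recipe.coast_col is not None:
        a[:, recipe.coast_col:] += recipe.water_offset_c
    return a


def _recenter_per_cell(a: np.ndarray, cmap: CellMap) -> np.ndarray:
    own = cmap.owner_flat
    flat = a.ravel()
    assigned = own >= 0
    cnt = np.bincount(own[assigned], minlength=cmap.n_cells).astype(float)
    s = np.bincount(own[assigned], weights=flat[assigned], minlength=cmap.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, s / cnt, 0.0)
    out = np.where(assigned, flat - mean[np.maximum(own, 0)], 0.0)
    return out.reshape(a.shape)


def make_truth(recipe: SceneRecipe) -> SyntheticTruth:
    """Build the anomaly field, per-day truth, and the hourly coarse cube.

    The coarse daily maximum is a smooth west-east gradient plus a seeded
    day-to-day scalar anomaly; the fine truth adds ``r_true * a`` so that
    its block mean over every coarse cell equals the coarse value exactly.
    The hourly cube samples a cosine diurnal cycle (in local standard time,
    peaking at ``peak_hour``) whose maximum is the coarse daily peak.
    """
    rng = np.random.default_rng(np.random.SeedSequence([recipe.seed, 0]))
    cmap = recipe.cell_map()
    a = _recenter_per_cell(_anomaly_raw(recipe), cmap)

    dates = pd.DatetimeIndex(recipe.dates).normalize().sort_values()
    nrc, ncc = recipe.coarse.shape

    # smooth static regional gradient across the coarse domain
    gx = np.linspace(-0.5, 0.5, ncc)[None, :]
    gy = np.linspace(-0.25, 0.25, nrc)[:, None]
    gradient = recipe.gradient_c * (gx + gy)

    # peaks for every calendar day spanning the requested dates (the hourly
    # cube needs a value for every hour of the contiguous span)
    span = pd.date_range(dates[0] - pd.Timedelta(days=1),
                         dates[-1] + pd.Timedelta(days=1), freq="D")
    w = rng.normal(0.0, recipe.weather_sd_c, size=len(span))
    peaks_span = recipe.base_mean_c + gradient[None, :, :] + w[:, None, None]

    day_pos = span.get_indexer(dates)
    coarse_tmax = peaks_span[day_pos]

    # fine truth: nearest-cell upsampling of the coarse peak + r_true * a
    own = cmap.owner_flat
    assigned = own >= 0
    nrf, ncf = recipe.fine.shape
    fine_tmax = np.full((len(dates), nrf, ncf), np.nan)
    up = np.full(own.shape, np.nan)
    for k in range(len(dates)):
        flat = coarse_tmax[k].ravel()
        up[:] = np.nan
        up[assigned] = flat[own[assigned]]
        fine_tmax[k] = (up + recipe.r_true * a.ravel()).reshape(nrf, ncf)

    cube = _hourly_cube(recipe, span, peaks_span)
    return SyntheticTruth(
        recipe=recipe, a=a, dates=dates, coarse_tmax=coarse_tmax,
        fine_tmax=fine_tmax, cube=cube, cmap=cmap,
    )


def _hourly_cube(
    recipe: SceneRecipe, span: pd.DatetimeIndex, peaks_span: np.ndarray
) -> HourlySeriesCube:
    lons = recipe.coarse.lon_centers()
    offsets = np.asarray(local_utc_offset(lons))  # per column, whole hours
    # UTC hours covering every local day of span[1:-1] for every offset
    t0 = np.datetime64(span[0], "ns")
    n_hours = 24 * len(span)
    times = t0 + np.arange(n_hours) * np.timedelta64(1, "h")

    nrc, ncc = recipe.coarse.shape
    values = np.full((n_hours, nrc, ncc), np.nan)
    hours_utc = np.arange(n_hours)  # hours since start of span
    for j, off in enumerate(offsets):
        h_local = hours_utc + int(off)  # local hours since span start
        day_idx = h_local // 24
        hod = h_local % 24
        inside = (day_idx >= 0) & (day_idx < len(span))
        di = np.clip(day_idx, 0, len(span) - 1)
        peak = peaks_span[di, :, j]  # (n_hours, nrc)
        phase = 2.0 * np.pi * (hod - recipe.peak_hour) / 24.0
        diurnal = 0.5 * recipe.base_amplitude_c * (1.0 - np.cos(phase))
        vals = peak - diurnal[:, None]
        vals[~inside] = np.nan
        values[:, :, j] = vals
    return HourlySeriesCube(spec=recipe.coarse, times=times, values=values)


def make_lst_stack(recipe: SceneRecipe, a: np.ndarray) -> SceneStack:
    """Generate the season's LST scenes over the anomaly field ``a``.

    Each scene is base LST + anomaly + Gaussian noise; seeded rectangular
    cloud masks remove roughly ``cloud_fraction`` of the area and a small
    fraction of the surviving pixels is pushed cold to mimic partial cloud
    contamination.
    """
    rng = np.random.default_rng(np.random.SeedSequence([recipe.seed, 1]))
    nr, nc = recipe.fine.shape
    values = np.zeros((recipe.n_scenes, nr, nc))
    valid = np.ones((recipe.n_scenes, nr, nc), dtype=bool)
    for s in range(recipe.n_scenes):
        scene = recipe.base_lst_c + a
        if recipe.noise_sd_c > 0:
            scene = scene + rng.normal(0.0, recipe.noise_sd_c, size=(nr, nc))
        mask = np.ones((nr, nc), dtype=bool)
        target = recipe.cloud_fraction * nr * nc
        # blocky clouds: random rectangles until the target area is covered
        guard = 0
        while (~mask).sum() < target and guard < 10_000:
            guard += 1
            h = int(rng.integers(5, max(6, nr // 4)))
            w = int(rng.integers(5, max(6, nc // 4)))
            r0 = int(rng.integers(0, max(1, nr - h + 1)))
            c0 = int(rng.integers(0, max(1, nc - w + 1)))
            mask[r0 : r0 + h, c0 : c0 + w] = False
        if recipe.contam_fraction > 0:
            contam = rng.random((nr, nc)) < recipe.contam_fraction
            scene = np.where(contam, scene + recipe.contam_offset_c, scene)
        values[s] = np.where(mask, scene, np.nan)
        valid[s] = mask
    labels = [f"period_{i + 1:02d}" for i in range(recipe.n_scenes)]
    return SceneStack(spec=recipe.fine, values=values, valid=valid,
                      labels=labels, season="synthetic warm season")


def make_stations(
    recipe: SceneRecipe,
    truth: SyntheticTruth,
    k: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Place ``k`` stations at seeded random fine-pixel centers and observe
    the fine truth there with observation noise.

    Returns the standard station table (station_id, lon, lat, date,
    obs_tmax_c) covering every date of the truth.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([recipe.seed if seed is None else seed, 2])
    )
    nr, nc = recipe.fine.shape
    rows = rng.integers(1, nr - 1, size=k)
    cols = rng.integers(1, nc - 1, size=k)
    lons = recipe.fine.lon_centers()[cols]
    lats = recipe.fine.lat_centers()[rows]

    records = []
    n_dates = len(truth.dates)
    noise = rng.normal(0.0, recipe.obs_noise_sd_c, size=(k, n_dates)) \
        if recipe.obs_noise_sd_c > 0 else np.zeros((k, n_dates))
    for i in range(k):
        sid = f"S{i:02d}"
        series = truth.fine_tmax[:, rows[i], cols[i]] + noise[i]
        for j, d in enumerate(truth.dates):
            records.append((sid, lons[i], lats[i], d, series[j]))
    return pd.DataFrame(
        records, columns=["station_id", "lon", "lat", "date", "obs_tmax_c"]
    )
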