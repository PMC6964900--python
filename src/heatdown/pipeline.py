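"""End-to-end pipeline over an on-disk workspace.

Workspace layout (as written by ``heatdown simulate`` and consumed by
``heatdown run``)::

    workspace/
      hourly.nc            hourly coarse 2 m air temperature (CF NetCDF)
      scenes/period_*.tif  scaled-integer LST scenes (raw Kelvin x 50, fill 0)
      stations.csv         station observations
      derived/             everything the pipeline writes

The stages are: daily extrema -> robust composite -> per-cell departures ->
downscaling -> station validation.  Each stage logs its counts (valid
pixels, fallback cells, dropped station rows) and the run writes a manifest
with a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .composite import (
    QC_FALLBACK_ZERO,
    QC_OK,
    SceneStack,
    compute_departures,
    ingest_scene,
    robust_composite,
    DEFAULT_LST_FILL,
    DEFAULT_LST_SCALE,
)
from .downscale import DownscaleConfig, downscale_constant_ratio
from .grids import Field2D, build_cell_map, extract_at_points
from .temporal import daily_extrema
from .validation import compute_stats, pair_series

log = logging.getLogger("heatdown")

__all__ = ["RunConfig", "run_pipeline", "load_scene_stack"]


@dataclass
class RunConfig:
    """Paths plus the knobs of a full pipeline run."""

    workspace: Path
    outdir: Path | None = None
    downscale: DownscaleConfig = field(default_factory=DownscaleConfig)
    lst_scale: float = DEFAULT_LST_SCALE
    lst_fill: float = DEFAULT_LST_FILL
    min_valid_pixels: int = 3
    month_start: int = 6
    month_end: int = 8
    years: list[int] | None = None  # default: infer from stations.csv
    validate: bool = True

    def __post_init__(self) -> None:
        self.workspace = Path(self.workspace)
        self.outdir = Path(self.outdir) if self.outdir else self.workspace / "derived"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["workspace"] = str(payload["workspace"])
        payload["outdir"] = str(payload["outdir"])
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_scene_stack(
    scenes_dir: Path, fill: float = DEFAULT_LST_FILL, scale: float = DEFAULT_LST_SCALE
) -> SceneStack:
    """Read a directory of scaled-integer LST GeoTIFFs into a SceneStack."""
    paths = sorted(Path(scenes_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no scene rasters (*.tif) in {scenes_dir}")
    values, valids, labels = [], [], []
    spec = None
    for p in paths:
        fld = hio.read_raster(p, fill=fill)
        # read_raster already dropped fill pixels; re-scale raw -> Celsius
        raw = np.where(fld.valid, fld.values, fill)
        celsius, valid = ingest_scene(raw, scale=scale, fill=fill)
        valid &= fld.valid
        values.append(np.where(valid, celsius, np.nan))
        valids.append(valid)
        labels.append(p.stem)
        if spec is None:
            spec = fld.spec
        elif not spec.matches(fld.spec):
            raise ValueError(f"scene {p.name} is not co-registered with the others")
    return SceneStack(
        spec=spec,
        values=np.stack(values),
        valid=np.stack(valids),
        labels=labels,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline over a workspace; returns the manifest.

    Raises with a stage-named message on the first failing stage.
    """
    ws = config.workspace
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}

    # ---- load inputs -----------------------------------------------------
    cube_path = ws / "hourly.nc"
    if not cube_path.exists():
        raise FileNotFoundError(f"[extrema] missing hourly cube {cube_path}")
    cube = hio.read_cube(cube_path)

    stations_path = ws / "stations.csv"
    stations = hio.read_stations(stations_path) if stations_path.exists() else None
    if config.validate and stations is None:
        raise FileNotFoundError(f"[validate] missing station table {stations_path}")

    years = config.years
    if years is None:
        if stations is None:
            raise ValueError("[validate] no years configured and no stations.csv")
        years = sorted(stations["date"].dt.year.unique().tolist())

    # candidate days: in the validation window AND with the full 24 local
    # hours covered by the cube for every pixel's longitude offset
    from .temporal import local_utc_offset

    offs = np.asarray(local_utc_offset(cube.spec.lon_centers()))
    hour = np.timedelta64(1, "h")
    t_lo, t_hi = cube.times[0], cube.times[-1] + hour
    dates = pd.DatetimeIndex(
        [
            t
            for t in pd.date_range(
                str(cube.times[0].astype("datetime64[D]")),
                str(cube.times[-1].astype("datetime64[D]")),
                freq="D",
            )
            if config.month_start <= t.month <= config.month_end
            and t.year in years
            and np.datetime64(t, "ns") - int(offs.max()) * hour >= t_lo
            and np.datetime64(t, "ns") + (24 - int(offs.min())) * hour <= t_hi
        ]
    )
    if len(dates) == 0:
        raise ValueError("[extrema] hourly cube covers no day of the validation window")

    # ---- composite + departures -----------------------------------------
    try:
        stack = load_scene_stack(ws / "scenes", fill=config.lst_fill,
                                 scale=config.lst_scale)
    except FileNotFoundError as e:
        raise FileNotFoundError(f"[composite] {e}") from e
    comp = robust_composite(stack)
    cmap = build_cell_map(stack.spec, cube.spec)
    dep = compute_departures(comp, cmap, min_valid_pixels=config.min_valid_pixels)
    n_fallback_cells = int(
        np.sum(
            np.bincount(
                cmap.owner_flat[(dep.qc.ravel() == QC_FALLBACK_ZERO)
                                & (cmap.owner_flat >= 0)],
                minlength=cmap.n_cells,
            )
            > 0
        )
    )
    manifest["stages"]["composite"] = {
        "n_scenes": stack.n_scenes,
        "valid_pixels": int(comp.valid.sum()),
        "fallback_cells": n_fallback_cells,
    }
    log.info("composite: %s", manifest["stages"]["composite"])
    hio.write_raster(Field2D(comp.spec, comp.t_h), out / "composite_t_h.tif")
    hio.write_raster(Field2D(dep.spec, dep.d), out / "departures_d.tif")
    hio.write_raster(
        Field2D(dep.spec, dep.qc.astype(float)), out / "departures_qc.tif"
    )

    # ---- daily extrema + downscale ---------------------------------------
    est_coarse, est_fine = [], []
    n_ok_pixels = int((dep.qc == QC_OK).sum())
    for date in dates:
        ext = daily_extrema(cube, date, with_min=False)
        dsc = downscale_constant_ratio(ext.tmax, dep, cmap, config.downscale)
        tag = date.strftime("%Y-%m-%d")
        hio.write_raster(ext.tmax, out / f"tmax_coarse_{tag}.nc", name="tmax")
        hio.write_raster(dsc.t_dis, out / f"tmax_downscaled_{tag}.tif")
        if stations is not None:
            meta = stations.drop_duplicates("station_id")[
                ["station_id", "lon", "lat"]
            ]
            vc, okc = extract_at_points(ext.tmax, meta["lon"], meta["lat"])
            vf, okf = extract_at_points(dsc.t_dis, meta["lon"], meta["lat"])
            for sid, a, oa, b, ob in zip(meta["station_id"], vc, okc, vf, okf):
                est_coarse.append((sid, date, a if oa else np.nan))
                est_fine.append((sid, date, b if ob else np.nan))
    manifest["stages"]["downscale"] = {
        "n_days": len(dates),
        "ok_pixels": n_ok_pixels,
        "ratio": config.downscale.r_ratio,
        "mode": config.downscale.mode,
    }
    log.info("downscale: %s", manifest["stages"]["downscale"])

    # ---- validation -------------------------------------------------------
    if config.validate and stations is not None:
        rows = []
        for label, est in (("coarse", est_coarse), ("downscaled", est_fine)):
            df = pd.DataFrame(est, columns=["station_id", "date", "estimate"])
            pairs = pair_series(df, stations, years,
                                config.month_start, config.month_end)
            for sid, p in pairs.items():
                if p.n == 0:
                    continue
                st = compute_stats(p)
                rows.append(
                    (sid, label, st.n, p.n_dropped, st.mean_diff, st.rmsd)
                )
        table = pd.DataFrame(
            rows,
            columns=["station_id", "product", "n", "n_dropped",
                     "mean_diff", "rmsd"],
        )
        table.to_csv(out / "validation.csv", index=False)
        manifest["stages"]["validate"] = {
            "n_stations": int(table["station_id"].nunique()),
            "dropped_rows": int(table["n_dropped"].sum()),
        }
        log.info("validate: %s", manifest["stages"]["validate"])

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
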