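"""Station validation: matched series, mean difference, RMSD, aggregation.

Gridded estimates (coarse or downscaled) are compared against station
observations by extracting the value of the pixel containing each station
and joining on (station, date) within a month-day window across years —
the standard evaluation is June-August over three years, giving 276
candidate days per station.  The metrics are the mean difference
(estimate minus observation, so negative means the grid runs cold) and the
root-mean-square difference.  City-level rows are aggregated as an
unweighted mean per metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "PairSeries",
    "ValidationStats",
    "candidate_dates",
    "pair_series",
    "compute_stats",
    "aggregate_cities",
    "round_half_up",
]


@dataclass
class PairSeries:
    """Matched (date, estimate, observation) rows for one station."""

    station_id: str
    frame: pd.DataFrame  # columns: date, estimate, observation
    n_dropped: int = 0  # candidate dates lost to a missing side

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ValidationStats:
    """Summary metrics of a matched series, in degrees Celsius."""

    n: int
    mean_diff: float
    rmsd: float


def candidate_dates(
    years: list[int], month_start: int = 6, month_end: int = 8
) -> pd.DatetimeIndex:
    """All calendar days with month in [month_start, month_end] for the
    given years (June-August of three years -> 276 days)."""
    if not years:
        raise ValueError("need at least one year")
    full = []
    for y in years:
        start = pd.Timestamp(year=y, month=month_start, day=1)
        end = pd.Timestamp(year=y, month=month_end, day=1) + pd.offsets.MonthEnd(0)
        full.append(pd.date_range(start, end, freq="D"))
    return full[0].append(full[1:]) if len(full) > 1 else full[0]


def pair_series(
    estimates: pd.DataFrame,
    stations: pd.DataFrame,
    years: list[int],
    month_start: int = 6,
    month_end: int = 8,
) -> dict[str, PairSeries]:
    """Join per-date gridded estimates with observations per station.

    ``estimates`` needs columns ``station_id, date, estimate``; ``stations``
    is the observation table (``station_id, date, obs_tmax_c``).  The join
    is restricted to the month-day window across the listed years; rows
    with either side missing (or NaN) are dropped and counted.
    """
    window = candidate_dates(years, month_start, month_end)
    if len(window) == 0:
        raise ValueError(
            f"empty validation window: months {month_start}-{month_end}, years {years}"
        )
    est = estimates.copy()
    est["date"] = pd.to_datetime(est["date"])
    obs = stations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    est = est[est["date"].isin(window)]
    obs = obs[obs["date"].isin(window)]

    merged = est.merge(
        obs[["station_id", "date", "obs_tmax_c"]],
        on=["station_id", "date"],
        how="inner",
    ).rename(columns={"obs_tmax_c": "observation"})
    merged = merged.sort_values(["station_id", "date"]).reset_index(drop=True)

    out: dict[str, PairSeries] = {}
    ids = sorted(set(est["station_id"]) | set(obs["station_id"]))
    any_rows = False
    for sid in ids:
        sub = merged[merged["station_id"] == sid]
        sub = sub.dropna(subset=["estimate", "observation"])
        n_dropped = len(window) - len(sub)
        frame = sub[["date", "estimate", "observation"]].reset_index(drop=True)
        out[sid] = PairSeries(station_id=sid, frame=frame, n_dropped=n_dropped)
        any_rows = any_rows or len(frame) > 0
    if not any_rows:
        raise ValueError(
            f"no overlapping estimate/observation dates in window "
            f"months {month_start}-{month_end}, years {years}"
        )
    return out


def compute_stats(p: PairSeries) -> ValidationStats:
    """Mean difference and RMSD of estimate minus observation."""
    if p.n < 1:
        raise ValueError(f"empty paired series for station {p.station_id}")
    diff = p.frame["estimate"].to_numpy() - p.frame["observation"].to_numpy()
    return ValidationStats(
        n=p.n,
        mean_diff=float(diff.mean()),
        rmsd=float(np.sqrt(np.mean(diff**2))),
    )


def aggregate_cities(per_city: pd.DataFrame) -> pd.Series:
    """Unweighted mean of each numeric metric column across city rows."""
    if len(per_city) < 1:
        raise ValueError("need at least one city")
    numeric = per_city.select_dtypes(include=[np.number])
    return numeric.mean(axis=0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as report tables are presented."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
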