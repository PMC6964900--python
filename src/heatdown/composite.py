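"""Robust warm-season LST compositing and per-cell departure fields.

Clear-sky satellite land-surface temperature comes in 8-day composite scenes
with fill values wherever cloud blocked the retrieval, plus occasional
erroneously *low* values from partial cloud contamination.  A season's worth
of scenes (May-September gives 19 eight-day periods) is collapsed per pixel
to the mean of the **upper half** of its valid values: with ``n`` valid
observations the top ``ceil(n/2)`` are averaged.  Taking only the upper half
discards both gaps and cold-contaminated retrievals, biasing the composite
toward genuine clear-sky conditions — which is exactly what a warm-season
thermal climatology should represent.

The departure field then re-centers the composite within each coarse cell:
``d = T_H - T_H,mean`` with ``T_H,mean`` the mean composite LST over the
cell's valid fine pixels.  These per-cell zero-mean departures are the
spatial pattern the downscaling step imposes; because they average to zero
within every cell, downscaling conserves the coarse field exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CellMap, GridSpec

__all__ = [
    "SceneStack",
    "RobustComposite",
    "DepartureField",
    "QC_OK",
    "QC_FALLBACK_ZERO",
    "QC_UNASSIGNED",
    "ingest_scene",
    "encode_scene",
    "robust_composite",
    "compute_departures",
]

KELVIN_OFFSET = 273.15
#: raw-to-Kelvin scale of MYD11A2-style scaled-integer LST rasters
DEFAULT_LST_SCALE = 0.02
#: raw fill value of those rasters (0 K is physically impossible)
DEFAULT_LST_FILL = 0

# per-pixel departure QC codes
QC_OK = 0  # departure computed from a well-populated cell
QC_FALLBACK_ZERO = 1  # pixel invalid or cell under-populated: d forced to 0
QC_UNASSIGNED = 2  # pixel center outside the coarse domain


@dataclass
class SceneStack:
    """A season of co-registered fine-resolution LST scenes.

    ``values`` has shape ``(n_scenes, nrows, ncols)`` in degrees Celsius,
    ``valid`` the matching cloud/fill mask.  ``labels`` identify the 8-day
    periods; ``season`` is a human-readable tag such as ``"2009 May-Sep"``.
    """

    spec: GridSpec
    values: np.ndarray
    valid: np.ndarray
    labels: list[str] = field(default_factory=list)
    season: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 3 or self.values.shape[1:] != self.spec.shape:
            raise ValueError("scene stack shape must be (n_scenes, nrows, ncols)")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape must match values")
        if not self.labels:
            self.labels = [f"scene_{i:02d}" for i in range(self.n_scenes)]

    @property
    def n_scenes(self) -> int:
        return self.values.shape[0]


@dataclass
class RobustComposite:
    """Upper-half-mean seasonal LST composite (the T_H surface)."""

    spec: GridSpec
    t_h: np.ndarray  # deg C, NaN where invalid
    n_valid: np.ndarray  # contributing scenes per pixel
    valid: np.ndarray


@dataclass
class DepartureField:
    """Per-pixel LST departures from the owning coarse cell's mean.

    ``d = T_H - T_H,mean`` over valid pixels of well-populated cells, zero
    elsewhere (see the QC codes).  ``cell_sigma`` is the population standard
    deviation of T_H over each cell's valid pixels; ``z = d / cell_sigma``
    is populated by :func:`heatdown.downscale.standardize`.
    """

    spec: GridSpec
    d: np.ndarray  # (nrows, ncols) deg C
    qc: np.ndarray  # (nrows, ncols) uint8, QC_* codes
    cell_mean: np.ndarray  # (n_cells,) deg C, NaN where undefined
    cell_sigma: np.ndarray  # (n_cells,) deg C, NaN where undefined
    owner: np.ndarray | None = None  # flat coarse index per fine pixel
    z: np.ndarray | None = None


def ingest_scene(
    raw: np.ndarray,
    scale: float = DEFAULT_LST_SCALE,
    fill: float = DEFAULT_LST_FILL,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a scaled-integer LST raster to degrees Celsius with a mask.

    Valid pixels map as ``raw * scale - 273.15``; raw values equal to
    ``fill`` are invalid, as is anything that would decode to a negative
    absolute temperature.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    raw = np.asarray(raw)
    valid = raw != fill
    kelvin = raw.astype(float) * scale
    bad = valid & (kelvin < 0)
    if bad.any():
        import warnings

        warnings.warn(
            f"{int(bad.sum())} pixel(s) decode to negative Kelvin; marked invalid",
            stacklevel=2,
        )
        valid &= ~bad
    celsius = np.where(valid, kelvin - KELVIN_OFFSET, np.nan)
    return celsius, valid


def encode_scene(
    celsius: np.ndarray,
    valid: np.ndarray | None = None,
    scale: float = DEFAULT_LST_SCALE,
    fill: int = DEFAULT_LST_FILL,
    dtype: str = "uint16",
) -> np.ndarray:
    """Inverse of :func:`ingest_scene`: Celsius to raw scaled integers.

    Quantization is to the nearest raw step (0.02 K by default, so the
    encode/decode round trip is accurate to 0.01 K).  Invalid pixels (and
    NaN) become the fill value.
    """
    celsius = np.asarray(celsius, dtype=float)
    if valid is None:
        valid = np.isfinite(celsius)
    raw = np.rint((celsius + KELVIN_OFFSET) / scale)
    raw = np.where(valid & np.isfinite(celsius), raw, fill)
    return raw.astype(dtype)


def robust_composite(stack: SceneStack) -> RobustComposite:
    """Per-pixel mean of the upper half of valid scene values.

    With ``n`` valid values the top ``ceil(n/2)`` are averaged; a pixel with
    no valid value in any scene is invalid.  Scene order is irrelevant.
    """
    if stack.n_scenes < 1:
        raise ValueError("scene stack is empty")
    vals = np.where(stack.valid, stack.values, np.nan)
    svals = np.sort(vals, axis=0)  # ascending, NaN sorted last
    n = stack.valid.sum(axis=0)  # (nr, nc)
    k = (n + 1) // 2  # ceil(n/2)

    body = np.nan_to_num(svals, nan=0.0)
    csum = np.concatenate(
        [np.zeros((1, *stack.spec.shape)), np.cumsum(body, axis=0)], axis=0
    )
    # sum of sorted values with ranks [n-k, n)
    idx_hi = n
    idx_lo = n - k
    nr, nc = stack.spec.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    top_sum = csum[idx_hi, rr, cc] - csum[idx_lo, rr, cc]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_h = np.where(n > 0, top_sum / np.maximum(k, 1), np.nan)
    valid = n > 0
    t_h = np.where(valid, t_h, np.nan)
    return RobustComposite(spec=stack.spec, t_h=t_h, n_valid=n, valid=valid)


def compute_departures(
    comp: RobustComposite, cmap: CellMap, min_valid_pixels: int = 3
) -> DepartureField:
    """Re-center the composite within each coarse cell.

    A cell needs at least ``min_valid_pixels`` valid member pixels for its
    statistics to be meaningful; below that, its pixels fall back to zero
    departure (the downscaled value then equals the coarse value) and are
    flagged.  ``cell_sigma`` uses the population (``n``) denominator — the
    cell's pixels are an enumeration of its area, not a sample.
    """
    if not comp.spec.matches(cmap.fine):
        raise ValueError("composite grid does not match the cell map's fine grid")

    own = cmap.owner_flat
    t_h = comp.t_h.ravel()
    valid = comp.valid.ravel()
    assigned = own >= 0
    use = assigned & valid

    n_cells = cmap.n_cells
    cnt = np.bincount(own[use], minlength=n_cells).astype(float)
    s1 = np.bincount(own[use], weights=t_h[use], minlength=n_cells)
    s2 = np.bincount(own[use], weights=t_h[use] ** 2, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, s1 / cnt, np.nan)
        var = np.where(cnt > 0, s2 / cnt - mean**2, np.nan)
    sigma = np.sqrt(np.maximum(var, 0.0))

    cell_ok = cnt >= min_valid_pixels
    mean = np.where(cell_ok, mean, np.nan)
    sigma = np.where(cell_ok, sigma, np.nan)

    pix_ok = use & cell_ok[np.maximum(own, 0)]
    d = np.zeros(own.shape)
    d[pix_ok] = t_h[pix_ok] - mean[own[pix_ok]]

    qc = np.full(own.shape, QC_FALLBACK_ZERO, dtype=np.uint8)
    qc[pix_ok] = QC_OK
    qc[~assigned] = QC_UNASSIGNED

    shape = comp.spec.shape
    return DepartureField(
        spec=comp.spec,
        d=d.reshape(shape),
        qc=qc.reshape(shape),
        cell_mean=mean,
        cell_sigma=sigma,
        owner=own.copy(),
    )
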