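"""The disaggregation step: impose normalized LST departures on coarse Tmax.

The model family is

    T_DIS = T_L + Z * sigma_L              (standardized form)
    Z     = (T_H - T_H,mean) / sigma_H
    T_DIS = T_L + (T_H - T_H,mean) * (sigma_L / sigma_H)

where T_L and sigma_L are the mean and standard deviation of the coarse
daily maximum air temperature over a spatial neighborhood of coarse cells
and T_H is the fine-resolution seasonal LST composite.  Because sigma_L
estimated from a neighborhood is unstable in strong climatological
gradients (and any neighborhood wider than one cell breaks conservation of
the coarse field), the operational form fixes the ratio sigma_L / sigma_H
as a constant R:

    T_DIS = T_L + R * (T_H - T_H,mean)

with R = 0.50 for daily maximum temperature, T_L the single owning cell's
value (no neighborhood averaging), and the departure field held fixed for
the warm season.  Air-temperature variations being smaller than LST
variations is what makes R < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .composite import QC_OK, DepartureField, RobustComposite
from .grids import CellMap, Field2D, GridSpec

__all__ = [
    "DEFAULT_R",
    "DownscaleConfig",
    "NeighborhoodStats",
    "DownscaledField",
    "standardize",
    "neighborhood_stats",
    "downscale_constant_ratio",
    "downscale_sigma_ratio",
    "estimate_sigma_ratio",
]

#: operational constant ratio sigma_L / sigma_H for daily maximum temperature
DEFAULT_R = 0.50


@dataclass(frozen=True)
class DownscaleConfig:
    """Configuration of the disaggregation step.

    ``r_ratio`` is the constant R; ``mode`` selects the constant-ratio form
    (default, the operational model) or the explicit sigma-ratio form;
    ``neighborhood_cells`` is the odd window width, in coarse cells, used to
    estimate sigma_L in sigma-ratio mode (1 = the owning cell alone).
    """

    r_ratio: float = DEFAULT_R
    mode: str = "constant_ratio"
    neighborhood_cells: int = 1

    def __post_init__(self) -> None:
        if self.r_ratio <= 0 and self.mode == "constant_ratio":
            # R = 0 is permitted as the degenerate "no sharpening" limit
            if self.r_ratio < 0:
                raise ValueError("r_ratio must be >= 0")
        if self.mode not in {"constant_ratio", "sigma_ratio"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.neighborhood_cells < 1 or self.neighborhood_cells % 2 == 0:
            raise ValueError("neighborhood_cells must be an odd integer >= 1")


@dataclass
class NeighborhoodStats:
    """Per-coarse-cell T_L and sigma_L over a window of coarse cells."""

    coarse: GridSpec
    t_l: np.ndarray  # (n_cells,) deg C, NaN invalid
    sigma_l: np.ndarray  # (n_cells,) deg C, NaN invalid


@dataclass
class DownscaledField:
    """The 1 km product T_DIS with QC propagated from the departures."""

    spec: GridSpec
    t_dis: Field2D
    qc: np.ndarray


def standardize(dep: DepartureField) -> DepartureField:
    """Populate Z = d / sigma_H per pixel; zero-sigma cells give Z = 0.

    Only OK-flagged pixels get a nonzero Z (d is zero elsewhere by
    construction).
    """
    if dep.owner is None:
        raise ValueError("departure field carries no ownership information")
    z = np.zeros_like(dep.d)
    flat_ok = (dep.qc == QC_OK).ravel()
    if flat_ok.any():
        s = dep.cell_sigma[dep.owner[flat_ok]]
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = np.where(s > 0, dep.d.ravel()[flat_ok] / s, 0.0)
        zflat = z.ravel()
        zflat[flat_ok] = zz
        z = zflat.reshape(dep.d.shape)
    return replace(dep, z=z)


def downscale_constant_ratio(
    tl: Field2D,
    dep: DepartureField,
    cmap: CellMap,
    cfg: DownscaleConfig | None = None,
) -> DownscaledField:
    """T_DIS = T_L + R * d, with T_L the owning coarse cell's daily max.

    Fine pixels whose owning cell has no valid T_L (or that are unassigned)
    come out invalid.  Where the departure QC is not OK, d is zero, so the
    output equals the coarse value exactly — the fallback is nearest-cell
    upsampling.
    """
    cfg = cfg or DownscaleConfig()
    if not tl.spec.matches(cmap.coarse):
        raise ValueError("coarse field grid does not match the cell map")
    if not dep.spec.matches(cmap.fine):
        raise ValueError("departure grid does not match the cell map")

    own = cmap.owner_flat
    assigned = own >= 0
    tl_flat = tl.masked().ravel()
    tl_up = np.full(own.shape, np.nan)
    tl_up[assigned] = tl_flat[own[assigned]]

    t_dis = tl_up + cfg.r_ratio * dep.d.ravel()
    shape = dep.spec.shape
    field = Field2D(dep.spec, t_dis.reshape(shape))
    return DownscaledField(spec=dep.spec, t_dis=field, qc=dep.qc.copy())


def neighborhood_stats(
    tl: Field2D, window: int = 1
) -> NeighborhoodStats:
    """Mean and population std of the coarse daily max over a window of
    coarse cells centered on each cell (clipped at the domain edge).

    ``window = 1`` degenerates to the cell itself: sigma_l = 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    vals = tl.masked()
    nr, nc = tl.spec.shape
    h = window // 2
    t_l = np.full(nr * nc, np.nan)
    s_l = np.full(nr * nc, np.nan)
    for r in range(nr):
        r0, r1 = max(0, r - h), min(nr, r + h + 1)
        for c in range(nc):
            c0, c1 = max(0, c - h), min(nc, c + h + 1)
            block = vals[r0:r1, c0:c1]
            good = np.isfinite(block)
            if not good.any():
                continue
            b = block[good]
            i = r * nc + c
            t_l[i] = b.mean()
            s_l[i] = b.std()  # population denominator
    return NeighborhoodStats(coarse=tl.spec, t_l=t_l, sigma_l=s_l)


def downscale_sigma_ratio(
    tl_stats: NeighborhoodStats,
    dep: DepartureField,
    cmap: CellMap,
) -> DownscaledField:
    """T_DIS = T_L + d * (sigma_L / sigma_H), the explicit-ratio form.

    Algebraically identical to T_L + Z * sigma_L.  Cells with sigma_H = 0
    (or undefined) contribute no adjustment: T_DIS = T_L there.
    """
    if not tl_stats.coarse.matches(cmap.coarse):
        raise ValueError("neighborhood stats grid does not match the cell map")
    if not dep.spec.matches(cmap.fine):
        raise ValueError("departure grid does not match the cell map")

    own = cmap.owner_flat
    assigned = own >= 0
    safe_own = np.maximum(own, 0)

    tl_up = np.where(assigned, tl_stats.t_l[safe_own], np.nan)
    sig_l = np.where(assigned, tl_stats.sigma_l[safe_own], np.nan)
    sig_h = np.where(assigned, dep.cell_sigma[safe_own], np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sig_h > 0, sig_l / sig_h, 0.0)
    ratio = np.where(np.isfinite(ratio), ratio, 0.0)

    t_dis = tl_up + dep.d.ravel() * ratio
    shape = dep.spec.shape
    field = Field2D(dep.spec, t_dis.reshape(shape))
    return DownscaledField(spec=dep.spec, t_dis=field, qc=dep.qc.copy())


def estimate_sigma_ratio(
    tl_fields: list[Field2D],
    comp: RobustComposite,
    cmap: CellMap,
    window: int = 3,
) -> tuple[np.ndarray, float]:
    """Diagnostic map and domain median of sigma_L / sigma_H.

    For each coarse cell, sigma_L is the population std of the coarse daily
    max over the ``window x window`` block of cells around it, averaged over
    the supplied days, and sigma_H is the population std of the composite
    LST over the fine pixels owned by that same block of cells.  Cells with
    degenerate sigma_H are omitted from the summary median.  Supports the
    choice (and validation) of the constant R.
    """
    if not tl_fields:
        raise ValueError("need at least one daily coarse field")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3 (need >= 2 cells)")
    coarse = cmap.coarse
    nrc, ncc = coarse.shape
    h = window // 2

    sig_l_days = np.zeros((len(tl_fields), nrc * ncc))
    sig_l_days[:] = np.nan
    for k, tl in enumerate(tl_fields):
        st = neighborhood_stats(tl, window=window)
        sig_l_days[k] = st.sigma_l
    with np.errstate(invalid="ignore"):
        sig_l = np.nanmean(sig_l_days, axis=0)

    # sigma_H over the window's fine pixels
    own = cmap.owner_flat
    t_h = comp.t_h.ravel()
    good = (own >= 0) & comp.valid.ravel()
    cnt = np.bincount(own[good], minlength=cmap.n_cells).astype(float)
    s1 = np.bincount(own[good], weights=t_h[good], minlength=cmap.n_cells)
    s2 = np.bincount(own[good], weights=t_h[good] ** 2, minlength=cmap.n_cells)

    cnt2 = cnt.reshape(nrc, ncc)
    s1g = s1.reshape(nrc, ncc)
    s2g = s2.reshape(nrc, ncc)
    sig_h = np.full(nrc * ncc, np.nan)
    for r in range(nrc):
        r0, r1 = max(0, r - h), min(nrc, r + h + 1)
        for c in range(ncc):
            c0, c1 = max(0, c - h), min(ncc, c + h + 1)
            n = cnt2[r0:r1, c0:c1].sum()
            if n < 2:
                continue
            m = s1g[r0:r1, c0:c1].sum() / n
            v = s2g[r0:r1, c0:c1].sum() / n - m * m
            sig_h[r * ncc + c] = np.sqrt(max(v, 0.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = sig_l / sig_h
    usable = np.isfinite(ratio) & (sig_h > 1e-12)
    ratio = np.where(usable, ratio, np.nan)
    if not usable.any():
        raise ValueError("no cell has a usable sigma_H; cannot summarize ratio")
    return ratio.reshape(nrc, ncc), float(np.nanmedian(ratio))
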