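"""Grid geometry, raster fields, and the fine-to-coarse cell ownership map.

All stages of the downscaling pipeline operate on regular geographic
(latitude/longitude) rasters.  The conventions here are fixed once and used
everywhere:

* pixel-center registration, row 0 at the north edge, column 0 at the west
  edge;
* pixel ``(r, c)`` covers the half-open box
  ``[west + c*dx, west + (c+1)*dx)`` in longitude and
  ``(north - (r+1)*dy, north - r*dy]`` in latitude, so the boxes tile the
  domain without overlap and every point of the domain belongs to exactly
  one pixel;
* pixel centers sit at ``west + (c+0.5)*dx``, ``north - (r+0.5)*dy``.

The half-open convention resolves all edge ties deterministically: a point
on a shared vertical edge belongs to the pixel to its east, a point on a
shared horizontal edge to the pixel above (north of) it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "Field2D",
    "CellMap",
    "build_cell_map",
    "extract_at_points",
]

#: owner value for a fine pixel whose center falls outside the coarse domain
UNASSIGNED = -1


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon raster.

    Parameters
    ----------
    west, north
        Longitude of the west edge and latitude of the north edge of the
        domain, in degrees.
    dx, dy
        Pixel width (longitude) and height (latitude) in degrees; both
        strictly positive.
    nrows, ncols
        Raster dimensions.
    """

    west: float
    north: float
    dx: float
    dy: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes dx, dy must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("nrows and ncols must be positive integers")

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.dx

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def size(self) -> int:
        return self.nrows * self.ncols

    def lon_centers(self) -> np.ndarray:
        """Longitudes of pixel centers, west to east."""
        return self.west + (np.arange(self.ncols) + 0.5) * self.dx

    def lat_centers(self) -> np.ndarray:
        """Latitudes of pixel centers, north to south (row order)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.dy

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinates as 2-D arrays of shape ``shape``."""
        lon = np.broadcast_to(self.lon_centers()[None, :], self.shape)
        lat = np.broadcast_to(self.lat_centers()[:, None], self.shape)
        return lon, lat

    def locate(
        self, lon: np.ndarray, lat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to containing pixels under the half-open box rule.

        Returns ``(row, col, inside)``; ``row``/``col`` are only meaningful
        where ``inside`` is True.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        u = (lon - self.west) / self.dx
        t = (self.north - lat) / self.dy
        col = np.floor(u).astype(np.int64)
        # latitude boxes are (south_edge, north_edge]: a point exactly on an
        # interior edge north - r*dy belongs to row r, which floor() gives;
        # the north edge itself (t == 0) also lands in row 0 via floor.
        row = np.floor(t).astype(np.int64)
        inside = (u >= 0) & (u < self.ncols) & (t >= 0) & (t < self.nrows)
        return row, col, inside

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Geometric equality within a floating tolerance."""
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class Field2D:
    """A raster of values (degrees Celsius throughout the pipeline) with a
    validity mask.

    Values at invalid pixels are never consumed by downstream math; they are
    stored as NaN for hygiene but the mask is authoritative.
    """

    spec: GridSpec
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.spec.shape:
                raise ValueError("valid mask shape does not match grid shape")
            self.valid = self.valid & np.isfinite(self.values)

    def masked(self) -> np.ndarray:
        """Values with invalid pixels as NaN."""
        return np.where(self.valid, self.values, np.nan)

    @classmethod
    def full(cls, spec: GridSpec, value: float) -> "Field2D":
        return cls(spec, np.full(spec.shape, float(value)))


@dataclass
class CellMap:
    """Ownership relation between a fine grid and a coarse grid.

    ``owner`` holds, for every fine pixel, the flat index of the coarse cell
    containing the fine pixel's *center* (or :data:`UNASSIGNED`).  ``members``
    is the inverse: for each coarse cell, the flat indices of the fine pixels
    it owns.  The two views are consistent by construction.
    """

    fine: GridSpec
    coarse: GridSpec
    owner: np.ndarray  # (nrows_fine, ncols_fine) int64, flat coarse index

    @property
    def n_cells(self) -> int:
        return self.coarse.size

    @property
    def owner_flat(self) -> np.ndarray:
        return self.owner.ravel()

    def members(self) -> list[np.ndarray]:
        """Flat fine-pixel indices owned by each coarse cell."""
        own = self.owner_flat
        assigned = own >= 0
        order = np.argsort(own[assigned], kind="stable")
        idx = np.flatnonzero(assigned)[order]
        counts = np.bincount(own[assigned], minlength=self.n_cells)
        splits = np.cumsum(counts)[:-1]
        return list(np.split(idx, splits))

    def cell_counts(self) -> np.ndarray:
        own = self.owner_flat
        return np.bincount(own[own >= 0], minlength=self.n_cells)


def build_cell_map(fine: GridSpec, coarse: GridSpec) -> CellMap:
    """Assign every fine pixel to the coarse cell containing its center.

    Any relative alignment of the two grids is permitted; fine pixels whose
    centers fall outside the coarse domain stay unassigned.  Zero overlap
    produces an empty map with a warning rather than an error.
    """
    lon, lat = fine.center_mesh()
    row, col, inside = coarse.locate(lon, lat)
    owner = np.where(inside, row * coarse.ncols + col, UNASSIGNED)
    if not inside.any():
        warnings.warn(
            "fine and coarse domains do not overlap: cell map is empty",
            stacklevel=2,
        )
    return CellMap(fine=fine, coarse=coarse, owner=owner.astype(np.int64))


def extract_at_points(
    field: Field2D, lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Value of the pixel containing each point (containment, not
    interpolation — gridded estimates are compared to stations directly).

    Returns ``(values, ok)``; points outside the domain or landing on an
    invalid pixel get NaN with ``ok = False``.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    row, col, inside = field.spec.locate(lon, lat)
    out = np.full(lon.shape, np.nan)
    ok = np.zeros(lon.shape, dtype=bool)
    r = row[inside]
    c = col[inside]
    vals = field.values[r, c]
    vmask = field.valid[r, c]
    tmp = np.where(vmask, vals, np.nan)
    out[inside] = tmp
    ok[inside] = vmask
    return out, ok
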