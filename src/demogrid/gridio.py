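"""Raster I/O and repair on the fixed 30 arc-second master lattice.

All surfaces in the pipeline — population counts, women-by-age-group counts,
fertility rates, births, pregnancies — live on a single global lattice of
1/120-degree (30 arc-second, ~1 km at the equator) cells anchored at
(-180 deg, +90 deg) in WGS84 geographic coordinates.  Inputs that are not on
this lattice are rejected rather than resampled: every downstream stage
conserves per-country counts, and silent resampling would break that.

GeoTIFF reading and writing is done with :mod:`tifffile`, carrying the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a minimal
EPSG:4326 GeoKey directory) plus the GDAL_NODATA convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile

__all__ = [
    "MASTER_CELL_SIZE",
    "MASTER_ANCHOR",
    "Grid",
    "GridError",
    "AlignmentError",
    "FormatError",
    "EmptySelectionError",
    "UnfillableError",
    "read_grid",
    "write_grid",
    "grid_info",
    "grids_aligned",
    "combine",
    "clip_to_country",
    "zonal_sum",
    "nibble",
]

#: Cell size of the master lattice, degrees (30 arc seconds).
MASTER_CELL_SIZE = 1.0 / 120.0

#: Upper-left anchor of the master lattice: (longitude, latitude) in degrees.
MASTER_ANCHOR = (-180.0, 90.0)

#: Absolute tolerance (degrees) when checking lattice alignment.  Far below
#: any coordinate round-off a GeoTIFF writer can introduce at float64.
_ALIGN_TOL = 1e-9

_CRS_TAG = "WGS84"

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKey directory: geographic model, pixel-is-area, EPSG:4326.
_GEOKEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


class GridError(Exception):
    """Base class for raster-layer errors."""


class AlignmentError(GridError):
    """A grid is not on the master lattice, or two grids do not align."""


class FormatError(GridError):
    """A raster file lacks required georeferencing or structure."""


class EmptySelectionError(GridError):
    """A clip or zonal selection matched no cells."""


class UnfillableError(GridError):
    """Nibble was asked to fill holes but no source cell exists."""


@dataclass
class Grid:
    """A single-band value surface on the master lattice.

    Parameters
    ----------
    values
        2-D array; units depend on role (persons, births, annual rate,
        integer zone/country codes).
    mask
        2-D boolean, ``True`` where the cell is nodata.  Masked values are
        never consumed by arithmetic.
    origin
        ``(longitude, latitude)`` of the upper-left corner, degrees.
    cell_size
        Lattice spacing in degrees; must equal :data:`MASTER_CELL_SIZE`.
    """

    values: np.ndarray
    mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float = MASTER_CELL_SIZE
    crs_tag: str = field(default=_CRS_TAG)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise FormatError(f"grid values must be 2-D, got ndim={self.values.ndim}")
        if self.mask.shape != self.values.shape:
            raise FormatError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        _check_lattice(self.origin, self.cell_size)

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        """Number of unmasked cells."""
        return int((~self.mask).sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the unmasked cell values."""
        return self.values[~self.mask]

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.mask.copy(), self.origin, self.cell_size)

    def cell_index(self) -> tuple[int, int]:
        """(row, col) of the upper-left cell on the global master lattice."""
        col = round((self.origin[0] - MASTER_ANCHOR[0]) / self.cell_size)
        row = round((MASTER_ANCHOR[1] - self.origin[1]) / self.cell_size)
        return row, col

    def total(self) -> float:
        """Sum over unmasked cells (0.0 for an all-masked grid)."""
        return float(self.values[~self.mask].sum()) if self.n_valid else 0.0


def _check_lattice(origin: tuple[float, float], cell_size: float) -> None:
    if abs(cell_size - MASTER_CELL_SIZE) > _ALIGN_TOL:
        raise AlignmentError(
            f"cell size {cell_size!r} deg is not the 30 arc-second master "
            f"lattice spacing {MASTER_CELL_SIZE!r}"
        )
    offsets = {
        "longitude": (origin[0] - MASTER_ANCHOR[0]) / cell_size,
        "latitude": (MASTER_ANCHOR[1] - origin[1]) / cell_size,
    }
    for name, offset in offsets.items():
        if abs(offset - round(offset)) * cell_size > _ALIGN_TOL:
            raise AlignmentError(
                f"origin {name} is offset {offset - round(offset):.3e} cells "
                f"from the master lattice anchored at {MASTER_ANCHOR}"
            )


def grids_aligned(a: Grid, b: Grid) -> bool:
    """True when two grids share origin, shape and cell size exactly."""
    return (
        a.shape == b.shape
        and a.cell_index() == b.cell_index()
        and abs(a.cell_size - b.cell_size) <= _ALIGN_TOL
    )


def _require_aligned(a: Grid, b: Grid, what: str = "grids") -> None:
    if not grids_aligned(a, b):
        raise AlignmentError(
            f"{what} are not on a common lattice window: "
            f"shapes {a.shape} vs {b.shape}, "
            f"lattice indices {a.cell_index()} vs {b.cell_index()}"
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path: str | Path, nodata: float | int | None = None) -> Path:
    """Write a :class:`Grid` as a single-band georeferenced GeoTIFF.

    Counts and rates are stored float64; integer code/zone grids int32.
    Masked cells are written as the nodata value (default -99 for integer
    grids, NaN-safe -9999.0 for float grids), recorded in the GDAL_NODATA tag.
    """
    path = Path(path)
    values = grid.values
    if np.issubdtype(values.dtype, np.integer) or values.dtype == bool:
        out = values.astype(np.int32, copy=True)
        fill = np.int32(-99 if nodata is None else nodata)
    else:
        out = values.astype(np.float64, copy=True)
        fill = np.float64(-9999.0 if nodata is None else nodata)
    out[grid.mask] = fill
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GEOKEYS, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        (_TAG_GDAL_NODATA, "s", 0, repr(fill.item())),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    return path


def read_grid(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF into a :class:`Grid`.

    Raises
    ------
    FormatError
        Missing georeferencing tags, multi-band file, or unreadable nodata.
    AlignmentError
        Cell size differs from 30 arc seconds, or the origin is not an
        integer number of cells from (-180, +90).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such raster file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise FormatError(f"{path}: expected a single band, got shape {values.shape}")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        if _TAG_GEOKEYS not in tags:
            raise FormatError(f"{path}: missing CRS (GeoKey directory)")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        origin = (float(tie[3]), float(tie[4]))
        if abs(sx - sy) > _ALIGN_TOL:
            raise AlignmentError(f"{path}: anisotropic cells ({sx}, {sy})")
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
    mask = np.zeros(values.shape, dtype=bool)
    if nodata_tag is not None:
        try:
            nodata = float(str(nodata_tag.value))
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable nodata tag {nodata_tag.value!r}") from exc
        mask = values == nodata
    return Grid(values=values, mask=mask, origin=origin, cell_size=float(sx))


def grid_info(path: str | Path) -> dict:
    """Lattice diagnostics for a raster file (CLI ``grid-info`` backend)."""
    g = read_grid(path)
    row, col = g.cell_index()
    return {
        "path": str(path),
        "shape": g.shape,
        "origin_lon": g.origin[0],
        "origin_lat": g.origin[1],
        "cell_size_deg": g.cell_size,
        "master_row": row,
        "master_col": col,
        "dtype": str(g.values.dtype),
        "n_valid": g.n_valid,
        "n_nodata": int(g.mask.sum()),
        "min": float(g.valid_values().min()) if g.n_valid else None,
        "max": float(g.valid_values().max()) if g.n_valid else None,
        "sum": g.total(),
        "crs": g.crs_tag,
    }


# ---------------------------------------------------------------------------
# Grid arithmetic
# ---------------------------------------------------------------------------

def combine(a: Grid, b: Grid, op: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> Grid:
    """Cellwise combination of two aligned grids.

    A cell is masked in the result if it is masked in either operand, so
    nodata never leaks into arithmetic.
    """
    _require_aligned(a, b)
    mask = a.mask | b.mask
    values = np.zeros(a.shape, dtype=np.float64)
    valid = ~mask
    values[valid] = op(
        a.values[valid].astype(np.float64), b.values[valid].astype(np.float64)
    )
    return Grid(values=values, mask=mask, origin=a.origin, cell_size=a.cell_size)


# ---------------------------------------------------------------------------
# Clip and nibble
# ---------------------------------------------------------------------------

def clip_to_country(g: Grid, codes: Grid, iso: int) -> Grid:
    """Restrict ``g`` to the cells of one country and crop to their bbox.

    Values are carried over exactly (no resampling); all cells whose country
    code differs from ``iso`` — or that are nodata in either input — are
    masked in the output.
    """
    _require_aligned(g, codes, "value grid and country-code grid")
    select = (~codes.mask) & (codes.values == iso) & (~g.mask)
    inside = (~codes.mask) & (codes.values == iso)
    if not inside.any():
        raise EmptySelectionError(f"country code {iso} not present in code grid")
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    values = g.values[r0:r1, c0:c1].copy()
    mask = ~select[r0:r1, c0:c1]
    origin = (
        g.origin[0] + c0 * g.cell_size,
        g.origin[1] - r0 * g.cell_size,
    )
    return Grid(values=values, mask=mask, origin=origin, cell_size=g.cell_size)


def zonal_sum(g: Grid, zones: Grid) -> dict[int, float]:
    """Sum of ``g`` over the unmasked cells of each zone id."""
    _require_aligned(g, zones, "value grid and zone grid")
    valid = (~g.mask) & (~zones.mask)
    ids = zones.values[valid].astype(np.int64)
    vals = g.values[valid].astype(np.float64)
    out: dict[int, float] = {}
    for zid in np.unique(ids):
        out[int(zid)] = float(vals[ids == zid].sum())
    return out


def nibble(zones: Grid, target_mask: np.ndarray) -> Grid:
    """Fill unassigned target cells with the id of the nearest assigned cell.

    Distance is Euclidean in cell units; ties are broken by row-major scan
    order of the assigned source cells, which makes the operation exactly
    reproducible.  Cells that already carry a zone id are never altered.

    Parameters
    ----------
    zones
        Integer zone grid; its ``mask`` marks unassigned cells.
    target_mask
        Boolean array marking cells that must end up with a valid id.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.shape != zones.shape:
        raise AlignmentError(
            f"target mask shape {target_mask.shape} != zone grid shape {zones.shape}"
        )
    assigned = ~zones.mask
    holes = target_mask & zones.mask
    if not holes.any():
        return zones.copy()
    if not assigned.any():
        raise UnfillableError("no assigned cell anywhere to nibble from")

    src = np.argwhere(assigned)           # row-major order — the tie rule
    hole_idx = np.argwhere(holes)
    src_vals = zones.values[assigned]

    values = zones.values.copy()
    mask = zones.mask.copy()
    # Exact integer squared distances; argmin takes the first minimum, which
    # is the row-major-first source cell.  Chunked to bound memory.
    chunk = max(1, 8_000_000 // max(len(src), 1))
    for start in range(0, len(hole_idx), chunk):
        block = hole_idx[start : start + chunk]
        d2 = (
            (block[:, 0:1].astype(np.int64) - src[:, 0].astype(np.int64)) ** 2
            + (block[:, 1:2].astype(np.int64) - src[:, 1].astype(np.int64)) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        values[block[:, 0], block[:, 1]] = src_vals[nearest]
        mask[block[:, 0], block[:, 1]] = False
    return Grid(values=values, mask=mask, origin=zones.origin, cell_size=zones.cell_size)
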