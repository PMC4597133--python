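"""Raster data model, geodesic helpers, and distribution preprocessing.

Everything downstream (gap scores, niche overlap, clustering) runs on a
single lattice type, :class:`GridLayer`: a north-up rectangular grid of
real values in geographic (longitude/latitude) coordinates with square
cells.  Distances are great-circle on a sphere of radius 6371 km — at the
50-km scale of occurrence buffers the error against an ellipsoid is well
below a cell width, and the spherical formula stays hand-checkable.

Raster I/O speaks the ESRI ASCII grid dialect (plain text ``.asc``), with
the nodata sentinel honoured bit-exactly on read and write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: membership of a cell in a point buffer is decided at the cell CENTER
BUFFER_AT_CELL_CENTER = True
#: default buffer radius for occurrence-based (CA50) distributions, km
DEFAULT_BUFFER_KM = 50.0
#: cells whose center latitude exceeds this are rejected by area bookkeeping
MAX_AREA_LATITUDE = 89.5
#: soil profile slices, cm, for the first metre of soil
SOIL_DEPTH_INTERVALS_CM = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100))

DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two grids that must share shape/origin/cell size do not."""


@dataclass
class GridLayer:
    """Georeferenced rectangular lattice of real values.

    ``values`` is a float array (rows x cols, row 0 northernmost); nodata
    cells are stored as NaN in memory and written out as ``nodata``.
    Cell (r, c) has its center at
    ``(origin_lon + (c + 0.5) * cell_size, origin_lat - (r + 0.5) * cell_size)``
    where ``origin`` is the upper-left corner of the grid.
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D matrix")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon[cols], lat[rows]) of the cell-center coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat - (rows + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing a point, or None if outside."""
        col = int(math.floor((lon - self.origin_lon) / self.cell_size))
        row = int(math.floor((self.origin_lat - lat) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def aligned_with(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and self.origin_lon == other.origin_lon
            and self.origin_lat == other.origin_lat
            and self.cell_size == other.cell_size
        )

    def require_aligned(self, other: "GridLayer", what: str = "layers") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} are not aligned: "
                f"{self.shape}@({self.origin_lon},{self.origin_lat},{self.cell_size}) vs "
                f"{other.shape}@({other.origin_lon},{other.origin_lat},{other.cell_size})"
            )

    # -- values -------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "GridLayer":
        return GridLayer(
            np.asarray(values, dtype=float),
            self.origin_lon,
            self.origin_lat,
            self.cell_size,
            self.nodata,
        )

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell area, broadcast to the grid shape.

        Area of a cell = (cell_size * pi/180 * R)^2 * cos(center latitude).
        Rows whose center latitude exceeds MAX_AREA_LATITUDE are rejected:
        the cosine model degenerates at the poles.
        """
        _, lat = self.cell_centers()
        if np.any(np.abs(lat) > MAX_AREA_LATITUDE):
            raise ValueError(
                f"cell center latitude beyond +/-{MAX_AREA_LATITUDE} deg; "
                "cosine-weighted areas are not defined there"
            )
        arc = self.cell_size * math.pi / 180.0 * EARTH_RADIUS_KM
        row_area = arc * arc * np.cos(np.radians(lat))
        return np.broadcast_to(row_area[:, None], self.shape)


class BinaryRange(GridLayer):
    """A GridLayer whose valid cells are exactly 0 or 1 (a presence range)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values[~np.isnan(self.values)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("BinaryRange cells must be 0, 1 or nodata")

    @property
    def cell_count(self) -> int:
        return int(np.nansum(self.values == 1.0))

    @property
    def area_km2(self) -> float:
        ones = self.values == 1.0
        if not ones.any():
            return 0.0
        return float(self.cell_areas_km2()[ones].sum())

    def copy_with(self, values: np.ndarray) -> "BinaryRange":
        return BinaryRange(
            np.asarray(values, dtype=float),
            self.origin_lon,
            self.origin_lat,
            self.cell_size,
            self.nodata,
        )

    @classmethod
    def from_layer(cls, layer: GridLayer, values: np.ndarray | None = None) -> "BinaryRange":
        vals = layer.values if values is None else values
        return cls(np.asarray(vals, dtype=float), layer.origin_lon, layer.origin_lat, layer.cell_size, layer.nodata)


# ---------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays; latitudes must lie in
    [-90, 90].
    """
    lat1a = np.asarray(lat1, dtype=float)
    lat2a = np.asarray(lat2, dtype=float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude out of [-90, 90]")
    p1, p2 = np.radians(lat1a), np.radians(lat2a)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def circular_buffer_range(
    points: Sequence[tuple[float, float]],
    radius_km: float = DEFAULT_BUFFER_KM,
    template: GridLayer | None = None,
) -> BinaryRange:
    """Union of geodesic circles of ``radius_km`` around occurrence points.

    A cell is presence (1) iff the great-circle distance from its CENTER
    to the nearest point is <= radius_km.  This is the CA50 distribution
    when radius_km is 50.
    """
    if template is None:
        raise ValueError("a template grid is required")
    pts = [(float(lo), float(la)) for lo, la in points]
    if not pts:
        raise ValueError("cannot build a buffer range from zero points")
    if not radius_km > 0:
        raise ValueError("radius_km must be positive")
    lon, lat = template.cell_centers()
    lon2 = np.broadcast_to(lon[None, :], template.shape)
    lat2 = np.broadcast_to(lat[:, None], template.shape)
    nearest = np.full(template.shape, np.inf)
    for plon, plat in pts:
        d = haversine_km(plon, plat, lon2, lat2)
        nearest = np.minimum(nearest, d)
    values = (nearest <= radius_km).astype(float)
    return BinaryRange.from_layer(template, values)


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def depth_weighted_soil(
    layers: Sequence[GridLayer],
    depth_intervals_cm: Sequence[tuple[float, float]] = SOIL_DEPTH_INTERVALS_CM,
) -> GridLayer:
    """Thickness-weighted mean of soil layers over the profile 0-100 cm.

    Weights are interval thickness / total thickness; intervals must be
    contiguous from 0.  nodata in any input propagates to the output.
    """
    if len(layers) != len(depth_intervals_cm):
        raise ValueError("one depth interval per layer required")
    expected_top = 0.0
    thicknesses = []
    for top, bottom in depth_intervals_cm:
        if top != expected_top or bottom <= top:
            raise ValueError("depth intervals must be contiguous from 0")
        thicknesses.append(bottom - top)
        expected_top = bottom
    base = layers[0]
    for lyr in layers[1:]:
        base.require_aligned(lyr, "soil depth layers")
    w = np.asarray(thicknesses, dtype=float)
    w = w / w.sum()
    stack = np.stack([lyr.values for lyr in layers])
    out = np.tensordot(w, stack, axes=1)
    out[np.isnan(stack).any(axis=0)] = np.nan
    return base.copy_with(out)


def apply_exclusion_mask(layer: GridLayer, mask: BinaryRange) -> GridLayer:
    """Drop cells flagged in the exclusion mask (urban/water/bare/ice).

    Masked cells become nodata and vanish from all downstream area and
    class bookkeeping.
    """
    layer.require_aligned(mask, "layer and exclusion mask")
    out = layer.values.copy()
    out[mask.values == 1.0] = np.nan
    return layer.copy_with(out)


def richness_map(ranges: Sequence[BinaryRange]) -> GridLayer:
    """Cell-wise count of presence across taxon ranges (taxon richness)."""
    ranges = list(ranges)
    if not ranges:
        raise ValueError("richness_map needs at least one range")
    base = ranges[0]
    total = np.zeros(base.shape)
    any_valid = np.zeros(base.shape, dtype=bool)
    for rng in ranges:
        base.require_aligned(rng, "richness ranges")
        total += np.nan_to_num(rng.values, nan=0.0)
        any_valid |= rng.valid_mask
    total[~any_valid] = np.nan
    return GridLayer(total, base.origin_lon, base.origin_lat, base.cell_size, base.nodata)


# ---------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> GridLayer:
    """Read a single-band ESRI ASCII grid (.asc).

    Supports xllcorner/yllcorner and xllcenter/yllcenter headers; the
    nodata sentinel is honoured exactly.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid {path} missing header key {req}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:
        xll = header["xllcenter"] - cell / 2.0
        yll = header["yllcenter"] - cell / 2.0
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(data_lines, dtype=float).reshape(nrows, ncols)
    values[values == nodata] = np.nan
    origin_lat = yll + nrows * cell
    return GridLayer(values, xll, origin_lat, cell, nodata)


def write_ascii_grid(layer: GridLayer, path: str | Path) -> None:
    """Write a GridLayer as an ESRI ASCII grid with a corner-origin header."""
    path = Path(path)
    vals = layer.values.copy()
    vals[np.isnan(vals)] = layer.nodata
    yll = layer.origin_lat - layer.n_rows * layer.cell_size
    with path.open("w") as fh:
        fh.write(f"ncols {layer.n_cols}\n")
        fh.write(f"nrows {layer.n_rows}\n")
        fh.write(f"xllcorner {float(layer.origin_lon)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(layer.cell_size)!r}\n")
        fh.write(f"nodata_value {float(layer.nodata)!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def resample_to(layer: GridLayer, template: GridLayer, categorical: bool = False) -> GridLayer:
    """Resample onto a coarser template grid.

    Continuous layers are mean-aggregated over contributing source cells;
    categorical layers take the nearest source cell to each template cell
    center.  Grids must share the same origin and the template cell size
    must be an integer multiple of the source cell size.
    """
    factor = template.cell_size / layer.cell_size
    k = round(factor)
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError("template cell size must be an integer multiple of source")
    if (layer.origin_lon, layer.origin_lat) != (template.origin_lon, template.origin_lat):
        raise AlignmentError("resampling requires a shared origin")
    if categorical:
        rows = (np.arange(template.n_rows) * k + k // 2).clip(0, layer.n_rows - 1)
        cols = (np.arange(template.n_cols) * k + k // 2).clip(0, layer.n_cols - 1)
        out = layer.values[np.ix_(rows, cols)]
    else:
        out = np.full(template.shape, np.nan)
        for r in range(template.n_rows):
            for c in range(template.n_cols):
                block = layer.values[r * k:(r + 1) * k, c * k:(c + 1) * k]
                if block.size and not np.all(np.isnan(block)):
                    out[r, c] = np.nanmean(block)
    return template.copy_with(out)
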