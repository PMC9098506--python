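"""Gridded-field data model and spatial primitives.

Everything downstream operates on 2-D geophysical fields (SST, sub-surface
salinity, habitat indicators/probabilities) living on a regular
latitude-longitude grid with cell-centre registration.  This module defines
the grid and field containers and the spatial building blocks:

* thickness-weighted depth averaging of layered (3-D) fields,
* bilinear regridding onto a common regular grid,
* extraction of the month of interest from a monthly series,
* spherical cell areas, and
* polygon region masks (cell-centre containment).

Conventions
-----------
Cells are half-open intervals ``[centre - step/2, centre + step/2)`` in both
axes; longitudes are normalised to ``[-180, 180)``; a boolean ``mask`` array
marks missing cells (``True`` = missing).  Masked source cells *poison*
bilinear interpolation: any target point whose 4-point stencil touches a
masked cell is masked in the output — a deliberately conservative rule near
coastlines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.geometry
import shapely.wkt
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "GridField",
    "LayeredField",
    "RegionPolygon",
    "GridError",
    "depth_average",
    "regrid_bilinear",
    "extract_month",
    "cell_areas",
    "region_mask",
    "field_to_dataset",
    "dataset_to_field",
    "layered_to_dataset",
    "dataset_to_layered",
    "read_region",
    "EARTH_RADIUS_KM",
]

#: Mean Earth radius used throughout for cell areas, km.
EARTH_RADIUS_KM = 6371.0

_SPACING_TOL = 1e-9

#: Variable vocabulary with canonical units (psu is dimensionless, CF "1").
VARIABLE_UNITS = {"sst": "degC", "salinity": "1", "probability": "1", "indicator": "1"}


class GridError(ValueError):
    """Invalid grid, field or polygon input."""


def _normalize_lon(lon: np.ndarray) -> np.ndarray:
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _check_uniform(centers: np.ndarray, name: str) -> float:
    if centers.ndim != 1 or centers.size < 1:
        raise GridError(f"{name} must be a non-empty 1-D array")
    if centers.size == 1:
        return 0.0
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise GridError(f"{name} must be strictly increasing")
    step = float(steps[0])
    if np.max(np.abs(steps - step)) > _SPACING_TOL:
        raise GridError(f"{name} spacing is not uniform (tolerance {_SPACING_TOL})")
    return step


@dataclass
class GridSpec:
    """Regular lat-lon grid, cell-centre registered.

    Parameters
    ----------
    lat_centers, lon_centers
        Strictly increasing, uniformly spaced cell-centre coordinates in
        degrees north / degrees east.  Longitudes are normalised to a single
        360-degree window ``[-180, 180)`` on construction.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray

    def __post_init__(self) -> None:
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        lon = _normalize_lon(self.lon_centers)
        if lon.size > 1 and np.any(np.diff(lon) <= 0):
            # a window like [170, 190] normalises non-monotonically; keep the
            # caller's increasing window instead (e.g. 170..190 stays as is)
            lon = np.asarray(self.lon_centers, dtype=float)
        self.lon_centers = lon
        _check_uniform(self.lat_centers, "lat_centers")
        _check_uniform(self.lon_centers, "lon_centers")
        if np.any(self.lat_centers <= -90.0) or np.any(self.lat_centers >= 90.0):
            raise GridError("latitude centers must lie strictly inside (-90, 90)")
        if np.ptp(self.lon_centers) >= 360.0:
            raise GridError("longitude centers must span less than 360 degrees")

    @classmethod
    def regular(
        cls,
        lat_min: float,
        lat_max: float,
        lon_min: float,
        lon_max: float,
        step: float = 0.5,
    ) -> "GridSpec":
        """Grid of cells with the given step whose centres tile the box."""
        lats = np.arange(lat_min + step / 2, lat_max, step)
        lons = np.arange(lon_min + step / 2, lon_max, step)
        return cls(lats, lons)

    @property
    def dlat(self) -> float:
        return float(self.lat_centers[1] - self.lat_centers[0]) if self.lat_centers.size > 1 else np.nan

    @property
    def dlon(self) -> float:
        return float(self.lon_centers[1] - self.lon_centers[0]) if self.lon_centers.size > 1 else np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers, atol=1e-9)
            and np.allclose(self.lon_centers, other.lon_centers, atol=1e-9)
        )


@dataclass
class GridField:
    """One 2-D variable on a :class:`GridSpec` at one (year, month).

    ``mask`` is True where the value is missing; values must be finite
    wherever unmasked.
    """

    grid: GridSpec
    variable: str
    values: np.ndarray
    time: tuple[int, int] | None = None  # (year, month)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.variable not in VARIABLE_UNITS:
            raise GridError(
                f"unknown variable {self.variable!r}; expected one of {sorted(VARIABLE_UNITS)}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise GridError("mask shape does not match values")
            self.mask = self.mask | ~np.isfinite(self.values)
        if self.time is not None:
            year, month = self.time
            if not 1 <= int(month) <= 12:
                raise GridError(f"month must be in 1..12, got {month}")
            self.time = (int(year), int(month))

    @property
    def year(self) -> int | None:
        return None if self.time is None else self.time[0]

    @property
    def month(self) -> int | None:
        return None if self.time is None else self.time[1]

    def masked_values(self) -> np.ndarray:
        """Values with masked cells as NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def with_values(self, values: np.ndarray, variable: str | None = None,
                    mask: np.ndarray | None = None) -> "GridField":
        return GridField(
            grid=self.grid,
            variable=self.variable if variable is None else variable,
            values=values,
            time=self.time,
            mask=self.mask if mask is None else mask,
        )


@dataclass
class LayeredField:
    """A 3-D (layer, lat, lon) field with depth-layer interfaces in metres."""

    grid: GridSpec
    variable: str
    interfaces: np.ndarray  # length n_layers + 1, increasing, metres
    values: np.ndarray  # (n_layers, n_lat, n_lon)
    time: tuple[int, int] | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.interfaces = np.asarray(self.interfaces, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.interfaces.ndim != 1 or self.interfaces.size < 2:
            raise GridError("interfaces must be 1-D with at least two entries")
        if np.any(np.diff(self.interfaces) <= 0):
            raise GridError("depth interfaces must be strictly increasing")
        expected = (self.interfaces.size - 1,) + self.grid.shape
        if self.values.shape != expected:
            raise GridError(f"values shape {self.values.shape} != {expected}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | ~np.isfinite(self.values)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.diff(self.interfaces)


@dataclass
class RegionPolygon:
    """Named polygon (possibly multi-part) in lon/lat degrees.

    Latitude caps such as "south of 70 N" are expressed as polygon edges.
    Polygons crossing the antimeridian must be supplied as multi-part rings.
    """

    name: str
    geometry: shapely.geometry.base.BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry.geom_type not in ("Polygon", "MultiPolygon"):
            raise GridError(f"region geometry must be (Multi)Polygon, got {self.geometry.geom_type}")
        if not self.geometry.is_valid:
            raise GridError(f"region {self.name!r}: polygon is invalid (self-intersection?)")

    @classmethod
    def from_vertices(cls, name: str, vertices: Sequence[tuple[float, float]]) -> "RegionPolygon":
        return cls(name, shapely.geometry.Polygon(vertices))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def depth_average(layered: LayeredField, zmin: float, zmax: float) -> GridField:
    """Thickness-weighted mean over the depth range ``[zmin, zmax]`` metres.

    Each layer contributes its value weighted by the thickness of its overlap
    with the requested range; columns with zero overlapping unmasked
    thickness come out masked.
    """
    if not zmin < zmax:
        raise GridError(f"require zmin < zmax, got [{zmin}, {zmax}]")
    top = layered.interfaces[:-1]
    bot = layered.interfaces[1:]
    clipped = np.clip(np.minimum(bot, zmax) - np.maximum(top, zmin), 0.0, None)
    if not np.any(clipped > 0):
        raise GridError(
            f"no depth layer overlaps [{zmin}, {zmax}] m; field spans "
            f"[{layered.interfaces[0]}, {layered.interfaces[-1]}] m"
        )
    w = clipped[:, None, None] * (~layered.mask)
    vals = np.where(layered.mask, 0.0, layered.values)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (vals * w).sum(axis=0) / wsum
    out_mask = wsum <= 0
    mean = np.where(out_mask, np.nan, mean)
    return GridField(layered.grid, layered.variable, mean, time=layered.time, mask=out_mask)


def regrid_bilinear(src: GridField, target: GridSpec) -> GridField:
    """Bilinear interpolation of ``src`` onto ``target`` cell centres.

    Target points outside the source centre domain are masked, as is any
    point whose interpolation stencil touches a masked source cell.
    """
    if src.grid.lat_centers.size < 2 or src.grid.lon_centers.size < 2:
        raise GridError("source grid needs at least 2 points per axis for bilinear interpolation")
    interp = RegularGridInterpolator(
        (src.grid.lat_centers, src.grid.lon_centers),
        src.masked_values(),
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    lat2, lon2 = np.meshgrid(target.lat_centers, target.lon_centers, indexing="ij")
    out = interp(np.column_stack([lat2.ravel(), lon2.ravel()])).reshape(target.shape)
    mask = ~np.isfinite(out)
    return GridField(target, src.variable, np.where(mask, np.nan, out), time=src.time, mask=mask)


def extract_month(series: Iterable[GridField], month: int) -> list[GridField]:
    """Fields for the given month, one per year, ordered by year.

    Years missing the month are omitted with a logged warning; duplicate
    (year, month) stamps are an error.
    """
    if not 1 <= month <= 12:
        raise GridError(f"month must be in 1..12, got {month}")
    series = list(series)
    seen: dict[tuple[int, int], int] = {}
    for f in series:
        if f.time is None:
            raise GridError("extract_month requires (year, month) stamps on every field")
        seen[f.time] = seen.get(f.time, 0) + 1
    dupes = sorted(t for t, n in seen.items() if n > 1)
    if dupes:
        raise GridError(f"duplicate (year, month) stamps: {dupes}")
    picked = sorted((f for f in series if f.month == month), key=lambda f: f.year)
    years_all = sorted({f.year for f in series})
    years_got = {f.year for f in picked}
    for y in years_all:
        if y not in years_got:
            logger.warning("extract_month: month %d missing for year %d; year omitted", month, y)
    return picked


def cell_areas(grid: GridSpec, earth_radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Spherical area of each cell in km², shape (n_lat, n_lon).

    ``A = R² Δλ (sin φ_top − sin φ_bottom)``; independent of longitude.
    """
    dlat = grid.dlat if grid.lat_centers.size > 1 else 0.5
    dlon = grid.dlon if grid.lon_centers.size > 1 else 0.5
    phi_top = np.radians(np.minimum(grid.lat_centers + dlat / 2, 90.0))
    phi_bot = np.radians(np.maximum(grid.lat_centers - dlat / 2, -90.0))
    band = earth_radius_km**2 * np.radians(dlon) * (np.sin(phi_top) - np.sin(phi_bot))
    return np.repeat(band[:, None], grid.lon_centers.size, axis=1)


def region_mask(grid: GridSpec, region: RegionPolygon) -> np.ndarray:
    """Boolean mask: True where the cell *centre* lies inside the polygon.

    Boundary points count as inside.  An empty intersection yields an
    all-False mask with a warning.
    """
    lat2, lon2 = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    inside = shapely.intersects_xy(region.geometry, lon2.ravel(), lat2.ravel())
    mask = inside.reshape(grid.shape)
    if not mask.any():
        warnings.warn(
            f"region {region.name!r} contains no cell centres of the grid",
            stacklevel=2,
        )
    return mask


# ---------------------------------------------------------------------------
# netCDF / polygon I/O
# ---------------------------------------------------------------------------

def _coords(grid: GridSpec) -> dict:
    return {
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }


def field_to_dataset(f: GridField, **attrs) -> xr.Dataset:
    """CF-style Dataset with dims (lat, lon); masked cells stored as NaN."""
    da = xr.DataArray(
        f.masked_values(),
        dims=("lat", "lon"),
        coords=_coords(f.grid),
        name=f.variable,
        attrs={"units": VARIABLE_UNITS[f.variable]},
    )
    ds = da.to_dataset()
    if f.time is not None:
        ds.attrs["year"], ds.attrs["month"] = f.time
    ds.attrs.update(attrs)
    return ds


def dataset_to_field(ds: xr.Dataset, variable: str) -> GridField:
    da = ds[variable]
    grid = GridSpec(ds["lat"].values, ds["lon"].values)
    time = None
    if "year" in ds.attrs and "month" in ds.attrs:
        time = (int(ds.attrs["year"]), int(ds.attrs["month"]))
    return GridField(grid, variable, da.values.astype(float), time=time)


def layered_to_dataset(f: LayeredField, **attrs) -> xr.Dataset:
    vals = f.values.copy()
    vals[f.mask] = np.nan
    mid = 0.5 * (f.interfaces[:-1] + f.interfaces[1:])
    da = xr.DataArray(
        vals,
        dims=("depth", "lat", "lon"),
        coords={"depth": ("depth", mid, {"units": "m"}), **_coords(f.grid)},
        name=f.variable,
        attrs={"units": VARIABLE_UNITS[f.variable]},
    )
    ds = da.to_dataset()
    ds["depth_bnds"] = xr.DataArray(f.interfaces, dims=("depth_edge",), attrs={"units": "m"})
    if f.time is not None:
        ds.attrs["year"], ds.attrs["month"] = f.time
    ds.attrs.update(attrs)
    return ds


def dataset_to_layered(ds: xr.Dataset, variable: str) -> LayeredField:
    grid = GridSpec(ds["lat"].values, ds["lon"].values)
    time = None
    if "year" in ds.attrs and "month" in ds.attrs:
        time = (int(ds.attrs["year"]), int(ds.attrs["month"]))
    return LayeredField(
        grid, variable, ds["depth_bnds"].values, ds[variable].values.astype(float), time=time
    )


def read_region(path: str, name: str | None = None) -> RegionPolygon:
    """Read a region polygon from a GeoJSON (.json/.geojson) or WKT file."""
    text = open(path).read().strip()
    if text.startswith("{"):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]
        props = obj.get("properties") or {}
        geom = shapely.geometry.shape(obj["geometry"] if "geometry" in obj else obj)
        return RegionPolygon(name or props.get("name", "region"), geom)
    return RegionPolygon(name or "region", shapely.wkt.loads(text))
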