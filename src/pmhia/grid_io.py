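"""Gridded and tabular input/output.

Handles the regular lat-lon working grid, CF-style NetCDF concentration
fields, country masks, spherical cell areas, conservative population
regridding, and the CSV table schemas shared by the rest of the pipeline.

Conventions
-----------
* Coordinates are cell centers; a cell is the half-open box
  ``[center - res/2, center + res/2)`` in both axes.
* Longitudes are kept on ``[-180, 180)``; fields read from files on
  ``[0, 360)`` are rotated (and their values reordered) on ingest.
* The Earth is a sphere of radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError, FormatError, GridError, SchemaError, ValidationError

EARTH_RADIUS_KM = 6371.0
#: country-code value marking sea / out-of-domain cells
SENTINEL_CODE = "--"

_SPACING_TOL = 1e-9
_CONC_UNITS = "ug m-3"


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid of cell centers.

    Parameters
    ----------
    lat : ndarray
        Cell-center latitudes, degrees north, strictly ascending.
    lon : ndarray
        Cell-center longitudes, degrees east on [-180, 180), strictly
        ascending.
    resolution : float
        Grid spacing in degrees, identical on both axes.
    """

    lat: np.ndarray
    lon: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        lat.setflags(write=False)
        lon.setflags(write=False)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, coord in (("lat", lat), ("lon", lon)):
            if coord.ndim != 1 or coord.size == 0:
                raise GridError(f"{name} must be a non-empty 1-D array")
            if coord.size > 1:
                steps = np.diff(coord)
                if np.any(steps <= 0):
                    raise GridError(f"{name} centers must be strictly ascending")
                if np.any(np.abs(steps - self.resolution) > _SPACING_TOL):
                    raise GridError(
                        f"{name} spacing deviates from resolution="
                        f"{self.resolution} by more than {_SPACING_TOL} deg"
                    )
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        if lat.min() < -90.0 or lat.max() > 90.0:
            raise GridError("latitudes must lie in [-90, 90]")
        if lon.min() < -180.0 or lon.max() >= 360.0:
            raise GridError("longitudes must lie in [-180, 360)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.lat.shape == other.lat.shape
            and self.lon.shape == other.lon.shape
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
            and self.resolution == other.resolution
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.lat.tobytes(), self.lon.tobytes(), self.resolution))

    def same_as(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Coordinate-wise equality within ``tol`` degrees."""
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=tol, rtol=0)
            and np.allclose(self.lon, other.lon, atol=tol, rtol=0)
        )

    @classmethod
    def from_coords(cls, lat: np.ndarray, lon: np.ndarray) -> "GridSpec":
        """Infer the resolution from coordinate arrays and validate."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        candidates = []
        for coord in (lat, lon):
            if coord.size > 1:
                candidates.append(float(np.diff(coord).mean()))
        if not candidates:
            raise GridError("cannot infer resolution from single-cell coordinates")
        res = candidates[0]
        if len(candidates) == 2 and abs(candidates[0] - candidates[1]) > _SPACING_TOL:
            raise GridError("lat and lon spacing differ; grid is not regular")
        return cls(lat=lat, lon=lon, resolution=res)

    @classmethod
    def regular(
        cls, lat_start: float, lon_start: float, nlat: int, nlon: int, resolution: float
    ) -> "GridSpec":
        """Build a grid from the south-west cell center and counts."""
        lat = lat_start + resolution * np.arange(nlat)
        lon = lon_start + resolution * np.arange(nlon)
        return cls(lat=lat, lon=lon, resolution=resolution)


def require_same_grid(*grids: GridSpec) -> None:
    """Raise :class:`GridError` unless all grids coincide."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_as(g):
            raise GridError("inputs are not on the same grid")


# ---------------------------------------------------------------------------
# gridded fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationField:
    """Annual-mean PM2.5 concentration on a :class:`GridSpec`.

    ``values`` is (nlat, nlon) in ug m-3; missing cells are NaN (never
    silently zero).  All finite values must be non-negative.
    """

    grid: GridSpec
    values: np.ndarray
    period_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != self.grid.shape:
            raise ValidationError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        finite = np.isfinite(values)
        if np.any(values[finite] < 0):
            raise ValidationError("concentration values must be non-negative")
        if np.any(np.isinf(values)):
            raise ValidationError("concentration values must be finite or NaN")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing (NaN) cells."""
        return ~np.isfinite(self.values)


@dataclass(frozen=True)
class CountryMask:
    """Per-cell ISO-3166-style alpha-2 country code; sea cells carry
    :data:`SENTINEL_CODE`."""

    grid: GridSpec
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=object)
        object.__setattr__(self, "codes", codes)
        if codes.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")

    def countries(self) -> list[str]:
        """Sorted unique non-sentinel codes present in the mask."""
        uniq = {str(c) for c in self.codes.ravel() if str(c) != SENTINEL_CODE}
        return sorted(uniq)


@dataclass(frozen=True)
class AreaField:
    """Cell areas in km^2 on a :class:`GridSpec`."""

    grid: GridSpec
    area: np.ndarray

    def __post_init__(self) -> None:
        area = np.asarray(self.area, dtype=float)
        area.setflags(write=False)
        object.__setattr__(self, "area", area)
        if area.shape != self.grid.shape:
            raise ValidationError("area shape does not match grid")
        if np.any(area <= 0):
            raise ValidationError("cell areas must be positive")


def cell_areas(grid: GridSpec) -> AreaField:
    """Spherical cell areas ``A = R^2 * dlam * (sin(lat_top) - sin(lat_bot))``.

    Cell edges sit at ``center +/- resolution/2``; a cell whose edge would
    cross a pole raises :class:`GridError`.
    """
    half = grid.resolution / 2.0
    top = grid.lat + half
    bot = grid.lat - half
    if np.any(top > 90.0 + _SPACING_TOL) or np.any(bot < -90.0 - _SPACING_TOL):
        raise GridError("grid cells cross a pole")
    dlam = np.deg2rad(grid.resolution)
    band = EARTH_RADIUS_KM**2 * dlam * (np.sin(np.deg2rad(top)) - np.sin(np.deg2rad(bot)))
    area = np.repeat(band[:, None], grid.lon.size, axis=1)
    return AreaField(grid=grid, area=area)


# ---------------------------------------------------------------------------
# NetCDF concentration I/O
# ---------------------------------------------------------------------------

def _canonicalize_lon(lon: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a [0, 360) longitude axis onto [-180, 180), reordering values."""
    if lon.size and lon.max() >= 180.0:
        lon = np.where(lon >= 180.0, lon - 360.0, lon)
        order = np.argsort(lon)
        lon = lon[order]
        values = values[..., order]
    return lon, values


def read_concentration(path: str | Path) -> ConcentrationField:
    """Read a CF-style NetCDF concentration field.

    Expects one 2-D variable with units ``"ug m-3"`` and 1-D ``lat``/``lon``
    coordinates in ``degrees_north``/``degrees_east``.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    names = [v for v in ds.data_vars if ds[v].ndim == 2]
    if len(names) != 1:
        raise FormatError(f"expected exactly one 2-D variable, found {names}")
    var = ds[names[0]]
    units = var.attrs.get("units")
    if units != _CONC_UNITS:
        raise FormatError(f"variable units {units!r}, expected {_CONC_UNITS!r}")
    for cname, expected in (("lat", "degrees_north"), ("lon", "degrees_east")):
        if cname not in var.dims:
            raise FormatError(f"missing coordinate {cname!r}")
        cunits = ds[cname].attrs.get("units")
        if cunits != expected:
            raise FormatError(f"coordinate {cname} units {cunits!r}, expected {expected!r}")
    var = var.transpose("lat", "lon")
    lon, values = _canonicalize_lon(
        np.asarray(ds["lon"].values, dtype=float),
        np.asarray(var.values, dtype=float),
    )
    grid = GridSpec.from_coords(np.asarray(ds["lat"].values, dtype=float), lon)
    return ConcentrationField(
        grid=grid, values=values, period_label=str(ds.attrs.get("period_label", ""))
    )


def write_concentration(field: ConcentrationField, path: str | Path) -> None:
    """Write a concentration field as CF-style NetCDF (dims lat, lon)."""
    if np.any(np.isinf(field.values)):
        raise ValidationError("cannot write non-finite concentrations")
    da = xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": field.grid.lat, "lon": field.grid.lon},
        name="pm25",
        attrs={"units": _CONC_UNITS, "long_name": "annual mean PM2.5 concentration"},
    )
    da["lat"].attrs["units"] = "degrees_north"
    da["lon"].attrs["units"] = "degrees_east"
    ds = da.to_dataset()
    ds.attrs["period_label"] = field.period_label
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# country mask I/O (long CSV: lat, lon, country)
# ---------------------------------------------------------------------------

def write_mask(mask: CountryMask, path: str | Path) -> None:
    lat_idx, lon_idx = np.meshgrid(
        np.arange(mask.grid.lat.size), np.arange(mask.grid.lon.size), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "lat": mask.grid.lat[lat_idx.ravel()],
            "lon": mask.grid.lon[lon_idx.ravel()],
            "country": [str(c) for c in mask.codes.ravel()],
        }
    )
    df.to_csv(path, index=False)


def read_mask(path: str | Path) -> CountryMask:
    df = pd.read_csv(path, dtype={"country": str}, comment="#")
    missing = {"lat", "lon", "country"} - set(df.columns)
    if missing:
        raise SchemaError(f"mask file missing columns {sorted(missing)}")
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    grid = GridSpec.from_coords(lat, lon)
    codes = np.full(grid.shape, SENTINEL_CODE, dtype=object)
    ilat = np.searchsorted(lat, df["lat"].to_numpy())
    ilon = np.searchsorted(lon, df["lon"].to_numpy())
    codes[ilat, ilon] = df["country"].to_numpy(dtype=object)
    return CountryMask(grid=grid, codes=codes)


# ---------------------------------------------------------------------------
# conservative population regridding
# ---------------------------------------------------------------------------

def _interval_overlap_weights(
    src_centers: np.ndarray,
    src_res: float,
    tgt_centers: np.ndarray,
    tgt_res: float,
    sin_space: bool,
) -> np.ndarray:
    """W[i, j] = fraction of source interval i overlapping target interval j.

    Latitude intervals are measured in sin(lat) so the fractions are true
    area fractions on the sphere.
    """

    def edges(centers: np.ndarray, res: float) -> tuple[np.ndarray, np.ndarray]:
        lo = centers - res / 2.0
        hi = centers + res / 2.0
        if sin_space:
            lo = np.sin(np.deg2rad(lo))
            hi = np.sin(np.deg2rad(hi))
        return lo, hi

    slo, shi = edges(src_centers, src_res)
    tlo, thi = edges(tgt_centers, tgt_res)
    overlap = np.maximum(
        0.0,
        np.minimum(shi[:, None], thi[None, :]) - np.maximum(slo[:, None], tlo[None, :]),
    )
    width = (shi - slo)[:, None]
    return overlap / width


def regrid_population(pop, target: GridSpec):
    """Conservatively aggregate a population grid onto ``target``.

    Each source cell's count is split among the target cells it overlaps in
    proportion to the spherical overlap area, so per-age-group totals are
    preserved whenever the source domain is contained in the target domain.

    Parameters
    ----------
    pop : demography.PopulationGrid
    target : GridSpec

    Returns
    -------
    demography.PopulationGrid on ``target``.
    """
    from .demography import PopulationGrid  # local import: avoids module cycle

    src = pop.grid
    if src.same_as(target):
        return pop
    w_lat = _interval_overlap_weights(
        src.lat, src.resolution, target.lat, target.resolution, sin_space=True
    )
    w_lon = _interval_overlap_weights(
        src.lon, src.resolution, target.lon, target.resolution, sin_space=False
    )
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise DomainError("source and target domains are disjoint")
    counts = np.einsum("ij,aik,kl->ajl", w_lat, pop.counts, w_lon, optimize=True)
    return PopulationGrid(
        grid=target, counts=counts, age_groups=pop.age_groups, year=pop.year
    )


# ---------------------------------------------------------------------------
# CSV table schemas
# ---------------------------------------------------------------------------

#: required column sets for each named table schema
TABLE_SCHEMAS: dict[str, list[str]] = {
    "baseline_rates": ["region", "endpoint", "age_group", "y0"],
    "projection_ratios": ["country", "age_group", "ratio"],
    "country_regions": ["country", "region"],
    "rr_params": [
        "family",
        "endpoint",
        "age_group",
        "theta",
        "theta_se",
        "alpha",
        "mu",
        "nu",
        "zcf",
    ],
}

_NON_NEGATIVE = {
    "baseline_rates": ["y0"],
    "projection_ratios": ["ratio"],
    "rr_params": ["theta_se", "zcf"],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV table and validate it against a named schema.

    Lines starting with ``#`` are treated as comments.  Unknown columns are
    rejected; rate/ratio columns are validated non-negative.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    required = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing required columns {missing}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        raise SchemaError(f"{schema} table has unknown columns {unknown}")
    df = df[required].copy()
    numeric = [c for c in required if c in ("y0", "ratio", "theta", "theta_se", "alpha", "mu", "nu", "zcf")]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _NON_NEGATIVE.get(schema, []):
        if (df[col] < 0).any():
            raise ValidationError(f"{schema}.{col} contains negative values")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a schema table as CSV, validating the column set first."""
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    required = TABLE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing required columns {missing}")
    df[required].to_csv(path, index=False)
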