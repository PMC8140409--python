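"""Age-structured population grids, national projection ratios, pyramids.

Population is carried as persons per cell per 5-year age band.  Mortality is
computed from age 25 upward; an optional ``under25`` band is carried for
pyramid displays only.  Sexes are merged on ingest — the data model holds
combined counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .grid_io import CountryMask, GridSpec, SENTINEL_CODE

#: the 12 modeled 5-year age bands, youngest to oldest
AGE_BANDS: tuple[str, ...] = (
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80plus",
)

#: optional display-only band, excluded from mortality computation
UNDER_25 = "under25"

ALL_AGES = "ALL_AGES"


@dataclass(frozen=True)
class PopulationGrid:
    """Persons per cell per age band on a regular lat-lon grid.

    ``counts`` has shape (n_age_groups, nlat, nlon); ``age_groups`` lists the
    band labels in the same order (the 12 modeled bands, optionally preceded
    or followed by ``under25``).
    """

    grid: GridSpec
    counts: np.ndarray
    age_groups: tuple[str, ...] = AGE_BANDS
    year: int = 2010

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        expected = (len(self.age_groups),) + self.grid.shape
        if counts.shape != expected:
            raise ValidationError(
                f"counts shape {counts.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(counts)):
            raise ValidationError("population counts must be finite")
        if np.any(counts < 0):
            raise ValidationError("population counts must be non-negative")
        unknown = set(self.age_groups) - set(AGE_BANDS) - {UNDER_25}
        if unknown:
            raise ValidationError(f"unknown age bands {sorted(unknown)}")
        if len(set(self.age_groups)) != len(self.age_groups):
            raise ValidationError("duplicate age bands")

    def band(self, age_group: str) -> np.ndarray:
        """Counts layer for one age band."""
        try:
            i = self.age_groups.index(age_group)
        except ValueError:
            raise CoverageError(f"age band {age_group!r} not carried") from None
        return self.counts[i]

    @property
    def modeled_bands(self) -> tuple[str, ...]:
        """Bands entering the mortality computation (25+)."""
        return tuple(a for a in self.age_groups if a != UNDER_25)


@dataclass(frozen=True)
class ProjectionRatios:
    """Country x age-band multipliers projecting 2010 population to 2050."""

    table: pd.DataFrame  # columns: country, age_group, ratio

    def __post_init__(self) -> None:
        df = self.table
        missing = {"country", "age_group", "ratio"} - set(df.columns)
        if missing:
            raise ValidationError(f"ratios table missing columns {sorted(missing)}")
        if (df["ratio"] < 0).any():
            raise ValidationError("projection ratios must be non-negative")
        if df.duplicated(["country", "age_group"]).any():
            raise ValidationError("duplicate (country, age_group) ratio rows")

    def ratio(self, country: str, age_group: str) -> float:
        sel = self.table[
            (self.table["country"] == country) & (self.table["age_group"] == age_group)
        ]
        if sel.empty:
            raise CoverageError(f"no projection ratio for ({country}, {age_group})")
        return float(sel["ratio"].iloc[0])


def apply_projection(
    pop: PopulationGrid, ratios: ProjectionRatios, mask: CountryMask, year: int = 2050
) -> PopulationGrid:
    """Scale each cell's band counts by the national projection ratio.

    The spatial pattern within a country is unchanged up to the scalar —
    no sub-national redistribution is modeled.  Cells with population but a
    sentinel country code raise :class:`CoverageError`.
    """
    if not pop.grid.same_as(mask.grid):
        raise ValidationError("population and mask are on different grids")
    sentinel = np.asarray(mask.codes == SENTINEL_CODE)
    if np.any(sentinel & (pop.counts.sum(axis=0) > 0)):
        raise CoverageError("populated cells carry the sentinel country code")
    scaled = pop.counts.copy()
    lut = {
        (r.country, r.age_group): r.ratio for r in ratios.table.itertuples(index=False)
    }
    for country in mask.countries():
        cells = np.asarray(mask.codes == country)
        for ai, band in enumerate(pop.age_groups):
            if band == UNDER_25 and (country, band) not in lut:
                continue  # display-only band may be left unprojected
            try:
                r = lut[(country, band)]
            except KeyError:
                raise CoverageError(
                    f"no projection ratio for ({country}, {band})"
                ) from None
            scaled[ai][cells] *= r
    return PopulationGrid(grid=pop.grid, counts=scaled, age_groups=pop.age_groups, year=year)


def age_pyramid(pop: PopulationGrid) -> pd.Series:
    """Share of total population per carried age band (sums to 1)."""
    totals = pop.counts.sum(axis=(1, 2))
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("cannot compute a pyramid for zero population")
    return pd.Series(totals / grand, index=list(pop.age_groups), name="share")


def total_population(pop: PopulationGrid, modeled_only: bool = False) -> float:
    """Total persons over all cells and bands (optionally 25+ bands only)."""
    if modeled_only:
        idx = [i for i, a in enumerate(pop.age_groups) if a != UNDER_25]
        return float(pop.counts[idx].sum())
    return float(pop.counts.sum())


# ---------------------------------------------------------------------------
# long-CSV population I/O (lat, lon, age_group, count)
# ---------------------------------------------------------------------------

def write_population(pop: PopulationGrid, path) -> None:
    frames = []
    lat_idx, lon_idx = np.meshgrid(
        np.arange(pop.grid.lat.size), np.arange(pop.grid.lon.size), indexing="ij"
    )
    for ai, band in enumerate(pop.age_groups):
        frames.append(
            pd.DataFrame(
                {
                    "lat": pop.grid.lat[lat_idx.ravel()],
                    "lon": pop.grid.lon[lon_idx.ravel()],
                    "age_group": band,
                    "count": pop.counts[ai].ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "year", pop.year)
    out.to_csv(path, index=False)


def read_population(path) -> PopulationGrid:
    df = pd.read_csv(path, comment="#")
    missing = {"lat", "lon", "age_group", "count"} - set(df.columns)
    if missing:
        raise ValidationError(f"population file missing columns {sorted(missing)}")
    year = int(df["year"].iloc[0]) if "year" in df.columns else 2010
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    grid = GridSpec.from_coords(lat, lon)
    bands = [b for b in (UNDER_25,) + AGE_BANDS if b in set(df["age_group"])]
    counts = np.zeros((len(bands),) + grid.shape)
    for ai, band in enumerate(bands):
        sub = df[df["age_group"] == band]
        ilat = np.searchsorted(lat, sub["lat"].to_numpy())
        ilon = np.searchsorted(lon, sub["lon"].to_numpy())
        counts[ai, ilat, ilon] = sub["count"].to_numpy()
    return PopulationGrid(grid=grid, counts=counts, age_groups=tuple(bands), year=year)
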