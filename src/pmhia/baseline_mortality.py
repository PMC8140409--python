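"""Region assignment and baseline mortality rates.

Europe is partitioned into three regions (Western, Central, Eastern) that
share socio-economic and climatic context; baseline mortality y0 is
resolved per region x endpoint x 5-year age band and is held constant
between the present and future scenarios.  Rates are stored as per-person
annual probabilities (deaths person^-1 yr^-1); per-100,000 sources are
converted on ingest.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .demography import AGE_BANDS
from .errors import CoverageError, ValidationError
from .exposure_response import Endpoint
from .grid_io import read_table

log = logging.getLogger(__name__)


class Region(str, enum.Enum):
    WESTERN = "Western"
    CENTRAL = "Central"
    EASTERN = "Eastern"


@dataclass(frozen=True)
class RegionScheme:
    """Total, non-overlapping mapping country code -> region."""

    mapping: dict[str, Region]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        for country, region in self.mapping.items():
            if not isinstance(region, Region):
                raise ValidationError(f"bad region {region!r} for {country!r}")

    def countries(self, region: Region | None = None) -> list[str]:
        if region is None:
            return sorted(self.mapping)
        return sorted(c for c, r in self.mapping.items() if r == region)


def assign_region(country: str, scheme: RegionScheme) -> Region:
    """Deterministic region label for a country code."""
    try:
        return scheme.mapping[country]
    except KeyError:
        raise CoverageError(f"country {country!r} not in the region scheme") from None


def load_region_scheme(source: str | Path | None = None) -> RegionScheme:
    """Load a country->region CSV; ``None`` loads the packaged default."""
    if source is None:
        source = resources.files("pmhia.data") / "country_regions.csv"
    df = read_table(source, "country_regions")
    if df["country"].duplicated().any():
        dups = sorted(df.loc[df["country"].duplicated(), "country"])
        raise ValidationError(f"countries assigned to more than one region: {dups}")
    return RegionScheme({r.country: Region(r.region) for r in df.itertuples(index=False)})


# ---------------------------------------------------------------------------
# baseline rates
# ---------------------------------------------------------------------------

#: coarse age bands accepted on ingest, broadcast to their 5-year members
COARSE_BANDS: dict[str, tuple[str, ...]] = {
    "25-44": ("25-29", "30-34", "35-39", "40-44"),
    "45-64": ("45-49", "50-54", "55-59", "60-64"),
    "65plus": ("65-69", "70-74", "75-79", "80plus"),
}


@dataclass(frozen=True)
class BaselineRates:
    """y0 per (region, endpoint, age band), deaths per person per year.

    The table must be complete over 3 regions x 7 endpoint slots (the six
    parameterized endpoints; other-NCD needs no rate of its own since it is
    derived by subtraction downstream) x 12 bands.
    """

    table: pd.DataFrame  # columns: region, endpoint, age_group, y0

    def __post_init__(self) -> None:
        df = self.table
        if (df["y0"] < 0).any() or (df["y0"] > 1).any():
            raise ValidationError("y0 must lie in [0, 1] (per-person annual rate)")
        if df.duplicated(["region", "endpoint", "age_group"]).any():
            raise ValidationError("duplicate (region, endpoint, age_group) rows")
        lut = {
            (Region(r.region), Endpoint(r.endpoint), r.age_group): float(r.y0)
            for r in df.itertuples(index=False)
        }
        object.__setattr__(self, "_lut", lut)
        for region in Region:
            for endpoint in Endpoint:
                for band in AGE_BANDS:
                    if (region, endpoint, band) not in lut:
                        raise CoverageError(
                            f"baseline rate missing for ({region.value}, "
                            f"{endpoint.value}, {band})"
                        )

    def y0(self, region: Region | str, endpoint: Endpoint | str, age_group: str) -> float:
        key = (Region(region), Endpoint(endpoint), age_group)
        try:
            return self._lut[key]
        except KeyError:
            raise CoverageError(f"no baseline rate for {key}") from None


def lookup_y0(
    rates: BaselineRates, region: Region | str, endpoint: Endpoint | str, age_group: str
) -> float:
    """Exact table lookup; a pure function of its arguments."""
    return rates.y0(region, endpoint, age_group)


def load_baseline_rates(
    source: str | Path, per_100k: bool = False
) -> BaselineRates:
    """Load a baseline_rates CSV.

    ``per_100k=True`` converts rates published per 100,000 person-years to
    per-person probabilities.  Coarse age bands (see :data:`COARSE_BANDS`)
    are broadcast to their constituent 5-year bands, with a log record.
    """
    df = read_table(source, "baseline_rates")
    if per_100k:
        df = df.assign(y0=df["y0"] / 1e5)
    rows = []
    for r in df.itertuples(index=False):
        if r.age_group in COARSE_BANDS:
            log.info(
                "broadcasting coarse band %s to %s for (%s, %s)",
                r.age_group, COARSE_BANDS[r.age_group], r.region, r.endpoint,
            )
            for band in COARSE_BANDS[r.age_group]:
                rows.append((r.region, r.endpoint, band, r.y0))
        else:
            rows.append((r.region, r.endpoint, r.age_group, r.y0))
    out = pd.DataFrame(rows, columns=["region", "endpoint", "age_group", "y0"])
    return BaselineRates(out)
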