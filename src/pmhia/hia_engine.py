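"""Attributable-mortality engine.

Applies the attributable-mortality equation

    dM = y0 * (RR - 1)/RR * Pop

per grid cell x endpoint x age band, with region-specific baseline rates
y0 and risk ratios RR evaluated at the cell's annual-mean PM2.5
concentration.  Derives the "other NCD" endpoint by subtracting the five
specific causes from the NCD+LRI envelope, and aggregates cell fields to
regional / age summaries and per-km^2 maps.

The all-cause ("All") column of the output tables is the NCD+LRI envelope
computed directly from its own risk function and all-cause baseline rates;
other-NCD is the residual of that envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline_mortality import BaselineRates, Region, RegionScheme, assign_region
from .demography import PopulationGrid, UNDER_25
from .errors import GridError, ValidationError
from .exposure_response import (
    Endpoint,
    ParamSet,
    RRValue,
    SPECIFIC_CAUSES,
    attributable_fraction,
)
from .grid_io import AreaField, ConcentrationField, CountryMask, GridSpec, SENTINEL_CODE

log = logging.getLogger(__name__)

#: endpoint label for the NCD+LRI envelope in reported tables
LABEL_ALL = "All"
#: endpoint label for the derived residual endpoint
LABEL_OTHER = "Other_NCD"
#: region label for the continental total rows
EUROPE = "EUROPE"
#: age label for the all-age total rows
ALL_AGE = "ALL"

_BOUNDS = ("central", "low", "high")


@dataclass(frozen=True)
class MortalityField:
    """Attributable deaths per year, per cell and age band, with CI layers.

    ``deaths`` has shape (3, n_bands, nlat, nlon); axis 0 is
    (central, low, high).
    """

    grid: GridSpec
    endpoint: str
    deaths: np.ndarray
    age_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        expected = (3, len(self.age_groups)) + self.grid.shape
        if deaths.shape != expected:
            raise ValidationError(f"deaths shape {deaths.shape}, expected {expected}")
        if not np.all(np.isfinite(deaths)):
            raise ValidationError("mortality field must be finite")
        c, lo, hi = deaths
        if np.any(lo > c + 1e-12) or np.any(c > hi + 1e-12):
            raise ValidationError("CI layers not ordered low <= central <= high")

    @property
    def central(self) -> np.ndarray:
        return self.deaths[0]

    def total(self) -> tuple[float, float, float]:
        """Domain total (central, low, high)."""
        return tuple(float(self.deaths[i].sum()) for i in range(3))


def cell_mortality(y0: float, rr: RRValue, pop: float) -> tuple[float, float, float]:
    """Attributable deaths in one cell: ``y0 * (RR - 1)/RR * pop`` per layer."""
    if not 0.0 <= y0 <= 1.0:
        raise ValidationError("y0 must lie in [0, 1]")
    if pop < 0:
        raise ValidationError("population must be non-negative")
    af = attributable_fraction(rr)
    return tuple(y0 * a * pop for a in af)


def _region_indices(
    mask: CountryMask, scheme: RegionScheme
) -> dict[Region, np.ndarray]:
    """Boolean cell masks per region; sentinel cells belong to no region."""
    out: dict[Region, np.ndarray] = {r: np.zeros(mask.grid.shape, dtype=bool) for r in Region}
    for country in mask.countries():
        region = assign_region(country, scheme)
        out[region] |= np.asarray(mask.codes == country)
    return out


def compute_endpoint(
    conc: ConcentrationField,
    pop: PopulationGrid,
    rates: BaselineRates,
    params: ParamSet,
    mask: CountryMask,
    scheme: RegionScheme,
    endpoint: Endpoint | str,
) -> MortalityField:
    """Apply the attributable-mortality equation for one endpoint.

    Per cell and age band: region from the mask, y0 lookup, RR at the cell
    concentration from the band-specific (or all-age) parameters, then
    ``dM = y0 * (RR-1)/RR * pop``.  Sentinel (sea / out-of-domain) cells and
    cells with missing concentration contribute zero.
    """
    endpoint = Endpoint(endpoint)
    for g in (pop.grid, mask.grid):
        if not conc.grid.same_as(g):
            raise GridError("concentration, population and mask grids differ")
    bands = tuple(a for a in pop.age_groups if a != UNDER_25)
    region_cells = _region_indices(mask, scheme)
    missing = conc.missing
    if missing.any():
        log.info("%s: %d cells with missing concentration contribute zero",
                 endpoint.value, int(missing.sum()))
    conc_values = np.where(missing, 0.0, conc.values)

    deaths = np.zeros((3, len(bands)) + conc.grid.shape)
    for ai, band in enumerate(bands):
        rr = params.evaluate(conc_values, endpoint, band)
        af = attributable_fraction(rr)
        pop_band = pop.band(band)
        for li, af_layer in enumerate(af):
            layer = np.zeros(conc.grid.shape)
            for region, cells in region_cells.items():
                if not cells.any():
                    continue
                y0 = rates.y0(region, endpoint, band)
                layer[cells] = y0 * af_layer[cells] * pop_band[cells]
            layer[missing] = 0.0
            deaths[li, ai] = layer
    # CI layers may invert where theta_se scaling is degenerate; they cannot
    # for theta_se >= 0, so order as computed
    return MortalityField(grid=conc.grid, endpoint=endpoint.value, deaths=deaths, age_groups=bands)


def compute_all_endpoints(
    conc: ConcentrationField,
    pop: PopulationGrid,
    rates: BaselineRates,
    params: ParamSet,
    mask: CountryMask,
    scheme: RegionScheme,
) -> dict[str, MortalityField]:
    """All six parameterized endpoints plus the derived other-NCD residual.

    Keys: the five specific causes, ``LABEL_ALL`` (the NCD+LRI envelope)
    and ``LABEL_OTHER``.
    """
    fields: dict[str, MortalityField] = {}
    for endpoint in SPECIFIC_CAUSES:
        fields[endpoint.value] = compute_endpoint(
            conc, pop, rates, params, mask, scheme, endpoint
        )
    envelope = compute_endpoint(conc, pop, rates, params, mask, scheme, Endpoint.NCD_LRI)
    envelope = MortalityField(
        grid=envelope.grid, endpoint=LABEL_ALL, deaths=envelope.deaths,
        age_groups=envelope.age_groups,
    )
    fields[LABEL_ALL] = envelope
    fields[LABEL_OTHER] = derive_other_ncd(
        envelope, [fields[e.value] for e in SPECIFIC_CAUSES]
    )
    return fields


def derive_other_ncd(
    all_cause: MortalityField, five_causes: list[MortalityField]
) -> MortalityField:
    """Other-NCD = NCD+LRI envelope minus the five specific causes.

    Cells driven negative by the subtraction are floored at zero; floor
    events are logged (count and largest clipped magnitude).
    """
    if len(five_causes) != len(SPECIFIC_CAUSES):
        raise ValidationError("expected exactly the five specific-cause fields")
    for f in five_causes:
        if f.age_groups != all_cause.age_groups or not f.grid.same_as(all_cause.grid):
            raise ValidationError("mismatched layer sets in other-NCD derivation")
    residual = all_cause.deaths - sum(f.deaths for f in five_causes)
    negative = residual < 0
    if negative.any():
        log.info(
            "other-NCD floored at 0 in %d layer-cells (largest clip %.3g)",
            int(negative.sum()), float(-residual[negative].min()),
        )
        residual = np.maximum(residual, 0.0)
    # independent CI-layer subtraction can invert bounds where the causes'
    # intervals are wider than the envelope's; clamp bounds to the central
    residual[1] = np.minimum(residual[1], residual[0])
    residual[2] = np.maximum(residual[2], residual[0])
    return MortalityField(
        grid=all_cause.grid, endpoint=LABEL_OTHER, deaths=residual,
        age_groups=all_cause.age_groups,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["region", "endpoint", "age_group", "central", "low", "high"]


def aggregate(
    field: MortalityField, mask: CountryMask, scheme: RegionScheme
) -> pd.DataFrame:
    """Regional summary: rows per region x age band, plus EUROPE and
    all-age (``ALL``) totals.  CI bounds are summed linearly.
    """
    if not field.grid.same_as(mask.grid):
        raise GridError("field and mask grids differ")
    region_cells = _region_indices(mask, scheme)
    rows = []
    for region in Region:
        cells = region_cells[region]
        for ai, band in enumerate(field.age_groups):
            vals = [float(field.deaths[li, ai][cells].sum()) for li in range(3)]
            rows.append([region.value, field.endpoint, band, *vals])
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    # all-age rows per region, then EUROPE rows as the sum over regions
    per_region = (
        df.groupby("region", sort=False)[["central", "low", "high"]].sum().reset_index()
    )
    per_region.insert(1, "endpoint", field.endpoint)
    per_region.insert(2, "age_group", ALL_AGE)
    europe_bands = (
        df.groupby("age_group", sort=False)[["central", "low", "high"]].sum().reset_index()
    )
    europe_bands.insert(0, "region", EUROPE)
    europe_bands.insert(1, "endpoint", field.endpoint)
    europe_total = pd.DataFrame(
        [[EUROPE, field.endpoint, ALL_AGE,
          per_region["central"].sum(), per_region["low"].sum(), per_region["high"].sum()]],
        columns=SUMMARY_COLUMNS,
    )
    return pd.concat([df, per_region, europe_bands, europe_total], ignore_index=True)


def summary_value(
    summary: pd.DataFrame,
    region: str = EUROPE,
    endpoint: str = LABEL_ALL,
    age_group: str = ALL_AGE,
    bound: str = "central",
) -> float:
    """Pull one cell out of a regional summary table."""
    if bound not in _BOUNDS:
        raise ValidationError(f"bound must be one of {_BOUNDS}")
    sel = summary[
        (summary["region"] == region)
        & (summary["endpoint"] == endpoint)
        & (summary["age_group"] == age_group)
    ]
    if sel.empty:
        raise ValidationError(f"no summary row ({region}, {endpoint}, {age_group})")
    return float(sel[bound].iloc[0])


def per_area(field: MortalityField, areas: AreaField) -> np.ndarray:
    """Deaths km^-2 yr^-1 per cell, summed over age bands; shape (3, nlat, nlon)."""
    if not field.grid.same_as(areas.grid):
        raise GridError("field and area grids differ")
    if np.any(areas.area == 0):
        raise ValidationError("zero-area cell")
    return field.deaths.sum(axis=1) / areas.area[None, :, :]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (so 72.57 -> 73)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def shares(summary: pd.DataFrame) -> pd.DataFrame:
    """Percentage of the all-cause EUROPE total per endpoint.

    ``summary`` must contain EUROPE/ALL rows for the endpoints of interest
    including the all-cause envelope.  Returns unrounded and
    integer-rounded percentages.
    """
    total = summary_value(summary, EUROPE, LABEL_ALL, ALL_AGE)
    if total <= 0:
        raise ValidationError("all-cause EUROPE total must be positive")
    rows = []
    for endpoint in summary["endpoint"].unique():
        value = summary_value(summary, EUROPE, endpoint, ALL_AGE)
        pct = 100.0 * value / total
        rows.append([endpoint, pct, round_half_away(pct)])
    return pd.DataFrame(rows, columns=["endpoint", "share_percent", "share_percent_rounded"])
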