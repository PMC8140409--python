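"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study conditions of a continental PM2.5 health
impact assessment on a desk-scale domain:

* a spatially smooth, strictly positive (lognormal) PM2.5 background with
  Gaussian urban hotspot plumes exceeding the 25 ug m-3 annual limit value;
* a future (RCP8.5-like) perturbation with a south-increase (+2 ug m-3) /
  north-decrease (-0.3 ug m-3) dipole about a latitude split;
* clustered population, partially co-located with the hotspots, whose age
  pyramid ages between scenarios (the 80plus share roughly doubles,
  4% -> 9%) while the total barely changes (808 -> 806 million);
* region-differentiated baseline mortality rates rising with age and from
  Western through Central to Eastern Europe;
* a toy 6-country / 3-region mask so no geographic boundary data is needed.

One global seed drives all sub-generators through independent derived
streams.  ``known_truth_case`` builds a 3-cell bundle whose expected
mortality summary is computed by an independent scalar (pure ``math``)
evaluation of the attributable-mortality equation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .baseline_mortality import BaselineRates, Region, RegionScheme
from .demography import AGE_BANDS, PopulationGrid, ProjectionRatios, UNDER_25
from .errors import ValidationError
from .exposure_response import Endpoint, ParamSet, SPECIFIC_CAUSES, load_rr_params
from .grid_io import ConcentrationField, CountryMask, GridSpec, SENTINEL_CODE
from .hia_engine import ALL_AGE, EUROPE, LABEL_ALL, LABEL_OTHER, SUMMARY_COLUMNS

_PYRAMID_BANDS = (UNDER_25,) + AGE_BANDS

#: present-day pyramid shares per band (under25 first); 80plus = 4%
PRESENT_SHARES = (
    0.32, 0.068, 0.070, 0.072, 0.072, 0.070, 0.064, 0.058,
    0.052, 0.044, 0.038, 0.032, 0.040,
)
#: 2050 pyramid shares; 80plus more than doubles to 9%
FUTURE_SHARES = (
    0.26, 0.056, 0.056, 0.058, 0.060, 0.062, 0.062, 0.062,
    0.064, 0.062, 0.058, 0.050, 0.090,
)


@dataclass(frozen=True)
class Hotspot:
    lat: float
    lon: float
    amplitude: float  # ug m-3 at the plume center
    radius: float  # degrees (Gaussian sigma)


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters; the defaults are the study conditions."""

    lat_start: float = 35.25
    lon_start: float = -9.75
    nlat: int = 40
    nlon: int = 60
    resolution: float = 0.5
    seed: int = 0

    # concentration background (lognormal) and hotspots
    background_median: float = 8.0  # ug m-3
    background_sigma: float = 0.35  # lognormal spread of the smooth field
    smoothness_cells: float = 3.0  # Gaussian-filter sigma, in cells
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(48.75, 2.25, 22.0, 0.7),
        Hotspot(50.25, 19.75, 24.0, 0.7),
        Hotspot(45.25, 9.25, 20.0, 0.6),
        Hotspot(40.25, -3.75, 20.0, 0.6),
    )

    # future dipole
    south_increment: float = 2.0  # ug m-3 added south of the split
    north_decrement: float = 0.3  # ug m-3 removed north of the split
    lat_split: float = 47.0
    split_width: float = 1.0  # degrees, logistic transition

    # population
    population_total: float = 808e6
    future_population_total: float = 806e6
    present_shares: tuple[float, ...] = PRESENT_SHARES
    future_shares: tuple[float, ...] = FUTURE_SHARES
    n_clusters: int = 25
    cluster_radius: float = 0.6  # degrees
    hotspot_colocation: float = 0.5  # fraction of hotspots seeding a cluster
    uniform_floor: float = 0.05  # share of population spread uniformly

    # baseline mortality shape
    age_rate_slope: float = 0.09  # per year of age, exponential rise
    region_gradient: tuple[float, float, float] = (1.0, 1.15, 1.35)  # W, C, E
    cause_scales: dict[str, float] = field(
        default_factory=lambda: {
            "IHD": 0.012, "CEV": 0.006, "COPD": 0.003, "LC": 0.004, "LRI": 0.002,
        }
    )
    envelope_factor: float = 1.5  # all-cause y0 = factor * sum of causes

    def __post_init__(self) -> None:
        for name, shares in (("present", self.present_shares), ("future", self.future_shares)):
            if abs(sum(shares) - 1.0) > 1e-9:
                raise ValidationError(f"{name} pyramid shares must sum to 1")
            if len(shares) != len(_PYRAMID_BANDS):
                raise ValidationError("pyramid shares must cover under25 + 12 bands")
        if self.background_median <= 0 or self.background_sigma < 0:
            raise ValidationError("background scales must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.regular(
            self.lat_start, self.lon_start, self.nlat, self.nlon, self.resolution
        )


def _stream(spec: SynthSpec, name: str) -> np.random.Generator:
    """Independent child stream derived from the one global seed."""
    # crc32 is stable across processes (unlike builtin str hashing)
    return np.random.default_rng([spec.seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# concentration
# ---------------------------------------------------------------------------

def _smooth_unit_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def synth_concentration(spec: SynthSpec) -> ConcentrationField:
    """Smooth lognormal background plus Gaussian hotspot plumes."""
    grid = spec.grid
    rng = _stream(spec, "concentration")
    gfield = _smooth_unit_field(rng, grid.shape, spec.smoothness_cells)
    values = spec.background_median * np.exp(spec.background_sigma * gfield)
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    for h in spec.hotspots:
        d2 = (lat2d - h.lat) ** 2 + (lon2d - h.lon) ** 2
        values = values + h.amplitude * np.exp(-d2 / (2.0 * h.radius**2))
    return ConcentrationField(grid=grid, values=values, period_label="1991-2010")


def synth_future_concentration(
    present: ConcentrationField, spec: SynthSpec
) -> ConcentrationField:
    """Apply the south-increase / north-decrease dipole, smoothed and clamped."""
    lat2d = np.repeat(present.grid.lat[:, None], present.grid.lon.size, axis=1)
    south_weight = 1.0 / (1.0 + np.exp((lat2d - spec.lat_split) / spec.split_width))
    delta = spec.south_increment * south_weight - spec.north_decrement * (1.0 - south_weight)
    values = np.maximum(0.0, present.values + delta)
    return ConcentrationField(
        grid=present.grid, values=values, period_label="2031-2050"
    )


# ---------------------------------------------------------------------------
# countries, population, projection
# ---------------------------------------------------------------------------

#: toy country codes per region, two per region, laid out west -> east
TOY_COUNTRIES: dict[str, Region] = {
    "W1": Region.WESTERN, "W2": Region.WESTERN,
    "C1": Region.CENTRAL, "C2": Region.CENTRAL,
    "E1": Region.EASTERN, "E2": Region.EASTERN,
}


def toy_region_scheme() -> RegionScheme:
    return RegionScheme(dict(TOY_COUNTRIES))


def toy_country_regions_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"country": list(TOY_COUNTRIES), "region": [r.value for r in TOY_COUNTRIES.values()]}
    )


def synth_country_mask(spec: SynthSpec) -> CountryMask:
    """Three longitude bands (W, C, E), each split at the domain mid-latitude."""
    grid = spec.grid
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    lon_lo, lon_hi = grid.lon.min(), grid.lon.max()
    third = (lon_hi - lon_lo) / 3.0
    lat_mid = 0.5 * (grid.lat.min() + grid.lat.max())
    codes = np.empty(grid.shape, dtype=object)
    west = lon2d < lon_lo + third
    east = lon2d >= lon_lo + 2 * third
    central = ~west & ~east
    for zone, prefix in ((west, "W"), (central, "C"), (east, "E")):
        codes[zone & (lat2d < lat_mid)] = f"{prefix}1"
        codes[zone & (lat2d >= lat_mid)] = f"{prefix}2"
    return CountryMask(grid=grid, codes=codes)


def synth_population(
    spec: SynthSpec,
) -> tuple[PopulationGrid, ProjectionRatios, CountryMask]:
    """Clustered settlements, national projection ratios and the toy mask.

    The age pyramid matches ``spec.present_shares`` exactly (the same
    spatial weight field is used for every band), and the projection ratios
    are built per band so that applying them reproduces the future pyramid
    and total.
    """
    grid = spec.grid
    rng = _stream(spec, "population")
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")

    weight = np.full(grid.shape, spec.uniform_floor / grid.lat.size / grid.lon.size)
    centers: list[tuple[float, float, float]] = []
    for h in spec.hotspots:
        if rng.random() < spec.hotspot_colocation:
            centers.append((h.lat, h.lon, spec.cluster_radius))
    while len(centers) < spec.n_clusters:
        centers.append(
            (
                rng.uniform(grid.lat.min(), grid.lat.max()),
                rng.uniform(grid.lon.min(), grid.lon.max()),
                spec.cluster_radius * rng.uniform(0.5, 1.5),
            )
        )
    sizes = rng.lognormal(mean=0.0, sigma=0.8, size=len(centers))
    cluster_field = np.zeros(grid.shape)
    for (clat, clon, cr), s in zip(centers, sizes):
        d2 = (lat2d - clat) ** 2 + (lon2d - clon) ** 2
        cluster_field += s * np.exp(-d2 / (2.0 * cr**2))
    cluster_field *= (1.0 - spec.uniform_floor) / cluster_field.sum()
    weight = weight + cluster_field
    weight /= weight.sum()

    counts = np.stack(
        [spec.population_total * share * weight for share in spec.present_shares]
    )
    pop = PopulationGrid(grid=grid, counts=counts, age_groups=_PYRAMID_BANDS, year=2010)

    mask = synth_country_mask(spec)
    rows = []
    for band, p_share, f_share in zip(
        _PYRAMID_BANDS, spec.present_shares, spec.future_shares
    ):
        ratio = (spec.future_population_total * f_share) / (
            spec.population_total * p_share
        )
        for country in TOY_COUNTRIES:
            rows.append([country, band, ratio])
    ratios = ProjectionRatios(pd.DataFrame(rows, columns=["country", "age_group", "ratio"]))
    return pop, ratios, mask


# ---------------------------------------------------------------------------
# baseline rates
# ---------------------------------------------------------------------------

_AGE_MIDPOINTS = {
    "25-29": 27.5, "30-34": 32.5, "35-39": 37.5, "40-44": 42.5, "45-49": 47.5,
    "50-54": 52.5, "55-59": 57.5, "60-64": 62.5, "65-69": 67.5, "70-74": 72.5,
    "75-79": 77.5, "80plus": 85.0,
}


def synth_baseline_rates(spec: SynthSpec) -> BaselineRates:
    """Deterministic rate table: exponential rise with age, Eastern >=
    Central >= Western, all-cause envelope >= sum of the five causes."""
    region_factor = dict(zip(Region, spec.region_gradient))
    rows = []
    for region in Region:
        for band in AGE_BANDS:
            age_term = math.exp(spec.age_rate_slope * (_AGE_MIDPOINTS[band] - 70.0))
            cause_sum = 0.0
            for cause, scale in spec.cause_scales.items():
                y0 = scale * age_term * region_factor[region]
                cause_sum += y0
                rows.append([region.value, cause, band, y0])
            rows.append([region.value, Endpoint.NCD_LRI.value, band,
                         spec.envelope_factor * cause_sum])
    df = pd.DataFrame(rows, columns=["region", "endpoint", "age_group", "y0"])
    return BaselineRates(df)


# ---------------------------------------------------------------------------
# known-truth case
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnownTruthBundle:
    """Tiny hand-computable input set plus its expected regional summary."""

    conc: ConcentrationField
    pop: PopulationGrid
    mask: CountryMask
    scheme: RegionScheme
    rates: BaselineRates
    params: ParamSet
    expected: pd.DataFrame  # SUMMARY_COLUMNS rows, one endpoint set per region


def _scalar_gemm_rr(c: float, theta: float, alpha: float, mu: float, nu: float,
                    zcf: float) -> float:
    """Independent scalar evaluation of the GEMM form (pure ``math``)."""
    z = max(0.0, c - zcf)
    omega = 1.0 / (1.0 + math.exp(-(z - mu) / nu))
    return math.exp(theta * math.log1p(z / alpha) * omega)


def known_truth_case(concentrations: tuple[float, float, float] = (12.4, 2.4, 20.0)):
    """3-cell domain (one country per region), two age bands, GEMM params.

    The expected summary is computed here by explicit scalar arithmetic —
    an independent path from the vectorized engine.  The middle cell sits
    exactly at the counterfactual, so it must contribute zero.
    """
    grid = GridSpec.regular(45.0, 0.0, 1, 3, 0.5)
    conc = ConcentrationField(
        grid=grid, values=np.array([list(concentrations)]), period_label="known-truth"
    )
    codes = np.array([["KW", "KC", "KE"]], dtype=object)
    mask = CountryMask(grid=grid, codes=codes)
    scheme = RegionScheme(
        {"KW": Region.WESTERN, "KC": Region.CENTRAL, "KE": Region.EASTERN}
    )
    bands = ("60-64", "80plus")
    pops = {"60-64": (2.0e6, 1.5e6, 3.0e6), "80plus": (4.0e5, 3.0e5, 8.0e5)}
    counts = np.array([[pops[b]] for b in bands]).reshape(len(bands), 1, 3)
    pop = PopulationGrid(grid=grid, counts=counts, age_groups=bands, year=2010)
    rates = synth_baseline_rates(SynthSpec())
    params = load_rr_params("GEMM")

    # --- independent scalar bookkeeping -----------------------------------
    region_of = {0: Region.WESTERN, 1: Region.CENTRAL, 2: Region.EASTERN}
    z = 1.96
    endpoint_names = [e.value for e in SPECIFIC_CAUSES] + [Endpoint.NCD_LRI.value]
    cellwise: dict[tuple[str, int, str], tuple[float, float, float]] = {}
    for name in endpoint_names:
        for cell in range(3):
            region = region_of[cell]
            c = concentrations[cell]
            for band in bands:
                p = params.lookup(name, band)
                y0 = rates.y0(region, name, band)
                npop = pops[band][cell]
                triple = []
                for theta in (p.theta, p.theta - z * p.theta_se, p.theta + z * p.theta_se):
                    rr = _scalar_gemm_rr(c, theta, p.alpha, p.mu, p.nu, p.zcf)
                    triple.append(y0 * (rr - 1.0) / rr * npop)
                cellwise[(name, cell, band)] = tuple(triple)
    # other-NCD per cell/band, floored at zero as the engine does
    for cell in range(3):
        for band in bands:
            env = cellwise[(Endpoint.NCD_LRI.value, cell, band)]
            sums = [
                sum(cellwise[(e.value, cell, band)][i] for e in SPECIFIC_CAUSES)
                for i in range(3)
            ]
            other = [max(0.0, env[i] - sums[i]) for i in range(3)]
            other[1] = min(other[1], other[0])
            other[2] = max(other[2], other[0])
            cellwise[(LABEL_OTHER, cell, band)] = tuple(other)

    display = {Endpoint.NCD_LRI.value: LABEL_ALL}
    rows = []
    for name in endpoint_names + [LABEL_OTHER]:
        label = display.get(name, name)
        region_totals = {}
        for cell in range(3):
            region = region_of[cell].value
            for band in bands:
                vals = cellwise[(name, cell, band)]
                rows.append([region, label, band, *vals])
            tot = [
                sum(cellwise[(name, cell, b)][i] for b in bands) for i in range(3)
            ]
            rows.append([region, label, ALL_AGE, *tot])
            region_totals[region] = tot
        europe_band = {
            b: [sum(cellwise[(name, cell, b)][i] for cell in range(3)) for i in range(3)]
            for b in bands
        }
        for b in bands:
            rows.append([EUROPE, label, b, *europe_band[b]])
        europe = [sum(t[i] for t in region_totals.values()) for i in range(3)]
        rows.append([EUROPE, label, ALL_AGE, *europe])
    expected = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return KnownTruthBundle(
        conc=conc, pop=pop, mask=mask, scheme=scheme, rates=rates,
        params=params, expected=expected,
    )


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_synthetic_bundle(spec: SynthSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete, validator-passing input bundle plus a run config.

    Returns the mapping of logical names to file paths.  Formats are exactly
    what :mod:`pmhia.grid_io` / :mod:`pmhia.demography` read back.
    """
    from . import demography as demo
    from . import grid_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    present = synth_concentration(spec)
    future = synth_future_concentration(present, spec)
    pop, ratios, mask = synth_population(spec)
    rates = synth_baseline_rates(spec)

    paths = {
        "concentration_present": outdir / "concentration_present.nc",
        "concentration_future": outdir / "concentration_future.nc",
        "population": outdir / "population.csv",
        "projection_ratios": outdir / "projection_ratios.csv",
        "mask": outdir / "mask.csv",
        "country_regions": outdir / "country_regions.csv",
        "baseline_rates": outdir / "baseline_rates.csv",
        "config": outdir / "config.yml",
    }
    grid_io.write_concentration(present, paths["concentration_present"])
    grid_io.write_concentration(future, paths["concentration_future"])
    demo.write_population(pop, paths["population"])
    grid_io.write_table(ratios.table, paths["projection_ratios"], "projection_ratios")
    grid_io.write_mask(mask, paths["mask"])
    grid_io.write_table(
        toy_country_regions_table(), paths["country_regions"], "country_regions"
    )
    grid_io.write_table(rates.table, paths["baseline_rates"], "baseline_rates")

    config = f"""# synthetic run configuration (seed={spec.seed})
shared:
  mask: mask.csv
  country_regions: country_regions.csv
  baseline_rates: baseline_rates.csv
  family: GEMM
present:
  label: "1991-2010"
  concentration: concentration_present.nc
  population: population.csv
future:
  label: "2031-2050"
  concentration: concentration_future.nc
  population: population.csv
  projection_ratios: projection_ratios.csv
"""
    paths["config"].write_text(config)
    return paths
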