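"""Present / future scenario runs, differencing and driver decomposition.

A scenario bundles one concentration field with one population state;
baseline mortality rates and risk-function parameters are shared between
scenarios (baseline rates are held constant in the future, and the
underlying concentration fields assume constant anthropogenic emissions so
their difference isolates the climate signal).

The change between scenarios is decomposed against the present reference:

    climate-only     = dM(future conc, present pop) - dM(present, present)
    population-only  = dM(present conc, future pop) - dM(present, present)
    interaction      = total change - climate-only - population-only

which sums to the total change exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline_mortality as bm
from . import demography, grid_io
from .baseline_mortality import BaselineRates, RegionScheme
from .demography import PopulationGrid
from .errors import ValidationError
from .exposure_response import Family, ParamSet, load_rr_params
from .grid_io import ConcentrationField, CountryMask
from .hia_engine import (
    MortalityField,
    SUMMARY_COLUMNS,
    aggregate,
    compute_all_endpoints,
    round_half_away,
)

_KEYS = ["region", "endpoint", "age_group"]


@dataclass(frozen=True)
class ScenarioConfig:
    """File-backed definition of one scenario run."""

    label: str
    concentration: Path
    population: Path
    mask: Path
    baseline_rates: Path
    projection_ratios: Path | None = None
    country_regions: Path | None = None  # None -> packaged default scheme
    rr_params: Path | None = None  # None -> packaged default table
    family: Family = Family.GEMM
    rates_per_100k: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("concentration", "population", "mask", "baseline_rates",
                     "projection_ratios", "country_regions", "rr_params"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} file not found: {p}")

    def input_paths(self) -> dict[str, Path]:
        out = {
            "concentration": self.concentration,
            "population": self.population,
            "mask": self.mask,
            "baseline_rates": self.baseline_rates,
        }
        for name in ("projection_ratios", "country_regions", "rr_params"):
            p = getattr(self, name)
            if p is not None:
                out[name] = p
        return out


@dataclass(frozen=True)
class ScenarioResult:
    """Gridded fields plus the regional summary for one scenario."""

    label: str
    fields: dict[str, MortalityField]
    summary: pd.DataFrame


def _load_shared(config: ScenarioConfig) -> tuple[CountryMask, RegionScheme, BaselineRates, ParamSet]:
    mask = grid_io.read_mask(config.mask)
    scheme = bm.load_region_scheme(config.country_regions)
    rates = bm.load_baseline_rates(config.baseline_rates, per_100k=config.rates_per_100k)
    params = load_rr_params(config.family, config.rr_params)
    return mask, scheme, rates, params


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run one scenario end to end; deterministic given its input files."""
    config.validate()
    conc = grid_io.read_concentration(config.concentration)
    pop = demography.read_population(config.population)
    mask, scheme, rates, params = _load_shared(config)
    if config.projection_ratios is not None:
        ratios = demography.ProjectionRatios(
            grid_io.read_table(config.projection_ratios, "projection_ratios")
        )
        pop = demography.apply_projection(pop, ratios, mask)
    fields = compute_all_endpoints(conc, pop, rates, params, mask, scheme)
    summary = combine_summaries(
        {name: aggregate(f, mask, scheme) for name, f in fields.items()}
    )
    return ScenarioResult(label=config.label, fields=fields, summary=summary)


def combine_summaries(per_endpoint: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-endpoint regional summaries into one table."""
    return pd.concat(per_endpoint.values(), ignore_index=True)


def delta_summary(present: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Rowwise future - present on matching (region, endpoint, age) rows."""
    merged = present.merge(future, on=_KEYS, suffixes=("_present", "_future"), how="inner")
    if len(merged) != len(present) or len(merged) != len(future):
        raise ValidationError("present and future summaries have different rows")
    out = merged[_KEYS].copy()
    for col in ("central", "low", "high"):
        out[col] = merged[f"{col}_future"] - merged[f"{col}_present"]
    return out


def percent_change(present: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """100 * (future - present) / present per summary row.

    Rows with a zero present value get NaN percentages and an
    ``undefined`` flag rather than raising.
    """
    merged = present.merge(future, on=_KEYS, suffixes=("_present", "_future"), how="inner")
    if len(merged) != len(present) or len(merged) != len(future):
        raise ValidationError("present and future summaries have different rows")
    out = merged[_KEYS].copy()
    p = merged["central_present"].to_numpy(dtype=float)
    f = merged["central_future"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (f - p) / p
    undefined = p == 0.0
    pct = np.where(undefined, np.nan, pct)
    out["present"] = p
    out["future"] = f
    out["change_percent"] = pct
    out["change_percent_rounded"] = [
        round_half_away(x) if np.isfinite(x) else pd.NA for x in pct
    ]
    out["undefined"] = undefined
    return out


def relative_excess(value: float, reference: float) -> float:
    """Difference from a reference expressed as a share of ``value``:
    ``100 * (value - reference) / value``.

    This is how cross-study excesses are quoted when the comparison base is
    the study's own estimate rather than the external reference.
    """
    if value == 0:
        raise ValidationError("relative excess undefined for a zero value")
    return 100.0 * (value - reference) / value


def decompose(
    present_conc: ConcentrationField,
    future_conc: ConcentrationField,
    present_pop: PopulationGrid,
    future_pop: PopulationGrid,
    rates: BaselineRates,
    params: ParamSet,
    mask: CountryMask,
    scheme: RegionScheme,
) -> dict[str, pd.DataFrame]:
    """Split the future-minus-present change into drivers.

    Returns delta summaries ``total``, ``climate_only``, ``population_only``
    and ``interaction``; the first equals the sum of the other three
    exactly (common present reference, no Shapley averaging).
    """

    def run(conc: ConcentrationField, pop: PopulationGrid) -> pd.DataFrame:
        fields = compute_all_endpoints(conc, pop, rates, params, mask, scheme)
        return combine_summaries({n: aggregate(f, mask, scheme) for n, f in fields.items()})

    base = run(present_conc, present_pop)
    conc_only = run(future_conc, present_pop)
    pop_only = run(present_conc, future_pop)
    both = run(future_conc, future_pop)

    total = delta_summary(base, both)
    climate = delta_summary(base, conc_only)
    population = delta_summary(base, pop_only)
    interaction = total[_KEYS].copy()
    for col in ("central", "low", "high"):
        interaction[col] = total[col] - climate[col] - population[col]
    return {
        "total": total,
        "climate_only": climate,
        "population_only": population,
        "interaction": interaction,
    }


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[ScenarioConfig, ScenarioConfig | None]:
    """Parse a YAML run config into (present, future-or-None) scenarios.

    Relative paths are resolved against the config file's directory.
    ``shared:`` keys apply to both scenarios; each scenario section may
    override them.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "present" not in raw:
        raise ValidationError("config must be a mapping with a 'present' section")
    shared = raw.get("shared", {}) or {}

    def build(section: dict, default_label: str) -> ScenarioConfig:
        merged = {**shared, **(section or {})}
        def p(key: str) -> Path | None:
            v = merged.get(key)
            return None if v in (None, "") else (path.parent / v)
        required = ("concentration", "population", "mask", "baseline_rates")
        for key in required:
            if p(key) is None:
                raise ValidationError(f"config missing required path {key!r}")
        return ScenarioConfig(
            label=str(merged.get("label", default_label)),
            concentration=p("concentration"),
            population=p("population"),
            mask=p("mask"),
            baseline_rates=p("baseline_rates"),
            projection_ratios=p("projection_ratios"),
            country_regions=p("country_regions"),
            rr_params=p("rr_params"),
            family=Family(merged.get("family", "GEMM")),
            rates_per_100k=bool(merged.get("rates_per_100k", False)),
            seed=int(merged.get("seed", 0)),
        )

    present = build(raw["present"], "present")
    future = build(raw["future"], "future") if raw.get("future") else None
    return present, future
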