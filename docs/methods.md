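# Methods

## Attributable mortality

The package applies the population-attributable-fraction form of the
exposure–response relationship per grid cell, endpoint and 5-year age band:

    ΔM = y0 · (RR − 1)/RR · Pop

`y0` is a per-person annual baseline mortality rate resolved by
region × endpoint × age band and held constant between scenarios, `Pop`
the cell population in the band (ages 25+; an optional under-25 band is
carried for pyramid displays only), and `RR` the risk ratio at the cell's
annual-mean PM2.5 concentration. Cells with a sentinel country code (sea,
out of domain) or missing concentration contribute zero and are logged,
never silently filled.

## Risk-ratio families

**GEMM.** `RR(z) = exp(θ·log(1 + z/α)·ω(z))` with logistic weight
`ω(z) = 1/(1 + exp(−(z − μ)/ν))` and `z = max(0, C − z_cf)`. The
counterfactual `z_cf` defaults to 2.4 μg m⁻³ (the lowest observed cohort
concentration in the GEMM cohort pool) and is configurable per parameter
row. Because `log(1 + z/α)` vanishes at `z = 0`, `RR(z_cf) = 1` holds
exactly, not approximately. Parameters (θ, SE, α, μ, ν per endpoint and
age band) ship in `pmhia/data/gemm_params.csv`. The all-age rows are the
widely reproduced GEMM constants; the age-specific slopes for IHD and CEV
— whose hazards decline with the logarithm of age — are constructed by
scaling the all-age slope with `ln(100/age_mid)` normalized to mean one
over the twelve bands, with SEs scaled by the same factor so each band's
z-score is preserved. The data-file header states this provenance; users
with access to cohort-derived band coefficients can supply their own CSV
via the same schema. COPD, LC and LRI are age-constant and served by
their all-age row.

**IER.** `RR(z) = 1 + a·(1 − exp(−γ·z^δ))`, the saturating family used by
the Global Burden of Disease; its shape constants are stored in the
(α, μ, ν) columns with family-specific meaning. No default IER table is
shipped; the family exists for sensitivity runs with user tables.

**Uncertainty.** 95% CIs propagate through the log-hazard slope only
(θ ∓ 1.96·SE); shape parameters carry no sampled uncertainty, matching how
GEMM-based assessments report CIs. CI bounds of aggregates are linear sums
of cell bounds — a deliberate simplification; printed bounds in published
tables of this kind are near but not exactly linear sums, so no test
asserts CI aggregation against external values.

## Endpoints and the "other NCD" residual

The all-cause ("All") column is the NCD+LRI envelope computed directly
from its own risk function with all-cause baseline rates; "other NCD" is
the cellwise residual after subtracting IHD, CEV, COPD, LC and LRI.
Residuals driven negative — possible where young-age cause-specific
hazards exceed the envelope — are floored at zero and logged. Flooring
makes endpoint shares super-additive by exactly the floored amount, which
is why the share table is reported against the envelope total rather than
forced to 100%. Where flooring inverts the independently summed CI layers,
bounds are clamped to the central value.

## Regions and baseline rates

Countries map to Western, Central and Eastern Europe via a packaged
ISO-3166 alpha-2 table (6 / 10 / 22 countries); user schemes are accepted
as CSV. Rates are stored per-person per-year; per-100 000 sources are
converted on ingest, and coarse bands (25–44, 45–64, 65+) broadcast to
their 5-year members with a log record. The rate table must be complete
over 3 regions × 6 parameterized endpoints × 12 bands.

## Grids, areas, regridding

Coordinates are cell centers on a regular lat–lon grid; cells are
half-open boxes `[center − Δ/2, center + Δ/2)`. Longitudes are normalized
to [−180, 180) on read. Cell areas use the spherical formula
`A = R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371 km (sub-0.3% error
versus an ellipsoid, irrelevant at this precision). Population regridding
is conservative: each source cell's count is split among overlapping
target cells in proportion to spherical overlap area (sin-latitude ×
longitude fractions), because population is extensive and summary tables
require mass conservation; bilinear interpolation would not conserve
totals. Concentration I/O is CF-style NetCDF (scipy backend,
NETCDF3_CLASSIC), tables are UTF-8 CSV with `#` comments.

## Scenario differencing and decomposition

Present and future runs share baseline rates and risk parameters; the
future differs in the concentration field and in the population (national
projection ratios by age band, uniform within a country — no sub-national
redistribution is modeled because only national ratios are derivable from
UN-style projections). Percent changes are `100·(future − present)/present`
per summary row, with zero-present rows flagged undefined rather than
raised; integer rounding is half-away-from-zero. Cross-study excesses are
quoted as `100·(value − reference)/value` (share of this study's own
estimate), the convention under which the published comparison figures
round correctly. The change decomposition holds the present as the common
reference: climate-only re-runs with future concentration and present
population, population-only vice versa, interaction is the remainder, so
the three terms sum to the total change exactly. Shapley-style averaging
over update orders was considered and rejected: the exact identity and
interpretability of a fixed reference outweigh symmetry here.

## Synthetic generator — what it emulates and what it does not

Defaults (the study conditions; one global seed drives independent
`crc32`-derived child streams):

| parameter | default | rationale |
|---|---|---|
| domain | 40 × 60 cells, 0.5°, lat 35–55, lon −10–20 | desk-scale stand-in for a 0.11° continental grid; totals are resolution-independent because the generator normalizes counts |
| background | lognormal, median 8 μg m⁻³, σ 0.35, smoothed | strictly positive, right-skewed annual-mean field |
| hotspots | 4 Gaussian plumes, 20–24 μg m⁻³ amplitude | urban cells exceed the 25 μg m⁻³ annual limit value |
| future dipole | +2.0 south / −0.3 north of 47°N, 1° logistic transition | southern climate penalty, northern wet-scavenging benefit |
| population | 808 × 10⁶ present, 806 × 10⁶ future | near-constant continental total |
| 80+ share | 4% → 9% | pronounced aging between scenarios |
| clusters | 25 Gaussian settlements, half co-located with hotspots | exposure–population correlation that drives hotspot mortality |
| baseline rates | exp(0.09·(age − 70)) age rise; region factors 1.0/1.15/1.35 (W/C/E); envelope = 1.5 × Σ causes | age-graded, region-graded, envelope-consistent |

The generator reproduces the *structure* the method assumes, not European
geography or census statistics: passing tests demonstrate correctness of
the arithmetic, conservation, monotonicity and determinism of the
pipeline, not the realism of any absolute mortality total. The toy
6-country mask exists so no boundary data is required.

`known_truth_case` builds a 3-cell, 2-band, one-country-per-region bundle
whose expected summary is computed by an independent scalar evaluation
(pure `math`, explicit loops) of the same equations; the engine must
reproduce every row to 1e-12 relative. One cell sits exactly at the
counterfactual and must contribute zero.

## Numerical choices and edge cases

- Exact unity at the counterfactual comes from `log1p(0) = 0`; no epsilon.
- RR evaluation rejects non-finite or negative concentrations; a central
  GEMM RR below 1 (impossible for θ > 0) is rejected by default.
- Attributable fractions of protective RRs (< 1) require an explicit
  opt-in and return negative values.
- Aggregation sums float64 cellwise values; conservation is asserted to
  1e-9 relative, regridding conservation to 1e-6, the known-truth oracle
  to 1e-12.
- Manifests are deterministic by default (checksums, versions, seed); a
  wall-clock timestamp is written only on request, so identical runs are
  byte-identical.
- Problem sizes in the test suite and acceptance script (40 × 60 default
  domain, 12–18-cell unit domains, 80 × 120 regrid source) are the
  package's chosen desk-scale conditions; every run completes in seconds.

## Known limitations

- No years-of-life-lost, morbidity or economic valuation.
- No Monte-Carlo uncertainty over GEMM shape parameters, and no
  uncertainty on baseline rates or population.
- Single country code per cell (no fractional coastline weighting).
- Conservative regridding assumes the source domain is contained in the
  target domain for exact conservation.
- The shipped age-specific IHD/CEV slopes are a documented construction
  anchored to the all-age coefficients, not cohort-derived band estimates.
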