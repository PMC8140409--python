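import logging

import numpy as np
import pandas as pd
import pytest

from pmhia.baseline_mortality import Region, RegionScheme
from pmhia.demography import PopulationGrid
from pmhia.errors import GridError, ValidationError
from pmhia.exposure_response import Endpoint, RRValue, load_rr_params
from pmhia.grid_io import ConcentrationField, CountryMask, GridSpec, cell_areas
from pmhia.hia_engine import (
    ALL_AGE,
    EUROPE,
    LABEL_ALL,
    LABEL_OTHER,
    MortalityField,
    aggregate,
    cell_mortality,
    compute_all_endpoints,
    compute_endpoint,
    derive_other_ncd,
    per_area,
    round_half_away,
    shares,
    summary_value,
)
from pmhia.synthetic_data import SynthSpec, known_truth_case, synth_baseline_rates

from conftest import max_rel_err


def single_region_world(nlat=1, nlon=1):
    grid = GridSpec.regular(45.0, 0.0, nlat, nlon, 0.5)
    mask = CountryMask(grid=grid, codes=np.full((nlat, nlon), "KW", dtype=object))
    scheme = RegionScheme({"KW": Region.WESTERN})
    return grid, mask, scheme


#: (region, all-cause thousands) printed-style fixture used in several tests
REGIONAL_ALL_CAUSE = {"Western": 166_000.0, "Central": 241_000.0, "Eastern": 497_000.0}


def regional_fixture_field(values_by_region):
    """One cell per region carrying a prescribed all-age value."""
    grid = GridSpec.regular(45.0, 0.0, 1, 3, 0.5)
    mask = CountryMask(grid=grid, codes=np.array([["KW", "KC", "KE"]], dtype=object))
    scheme = RegionScheme({"KW": Region.WESTERN, "KC": Region.CENTRAL, "KE": Region.EASTERN})
    vals = np.array(
        [[values_by_region["Western"], values_by_region["Central"], values_by_region["Eastern"]]],
        dtype=float,
    )  # (nlat=1, nlon=3)
    deaths = np.repeat(vals[None, None, :, :], 3, axis=0)  # (3 layers, 1 band, 1, 3)
    field = MortalityField(grid=grid, endpoint=LABEL_ALL, deaths=deaths, age_groups=("60-64",))
    return field, mask, scheme


class TestCellMortality:
    def test_no_excess_risk(self):
        assert cell_mortality(0.01, RRValue(1.0, 1.0, 1.0), 1e5) == (0.0, 0.0, 0.0)

    def test_zero_population(self):
        assert cell_mortality(0.01, RRValue(1.25, 1.2, 1.3), 0.0) == (0.0, 0.0, 0.0)

    def test_hand_value(self):
        # 0.01 * (0.25/1.25) * 100000 = 200
        dm = cell_mortality(0.01, RRValue(1.25, 1.25, 1.25), 100_000.0)
        assert dm[0] == pytest.approx(200.0, rel=1e-12)

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            cell_mortality(0.01, RRValue(1.25, 1.25, 1.25), -1.0)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValidationError):
            cell_mortality(1.5, RRValue(1.25, 1.25, 1.25), 10.0)


class TestComputeEndpoint:
    def setup_method(self):
        self.params = load_rr_params("GEMM")
        self.rates = synth_baseline_rates(SynthSpec())

    def test_uniform_counterfactual_gives_zero_field(self):
        grid, mask, scheme = single_region_world(2, 3)
        conc = ConcentrationField(grid=grid, values=np.full((2, 3), 2.4))
        pop = PopulationGrid(grid=grid, counts=np.full((12, 2, 3), 1e4))
        field = compute_endpoint(conc, pop, self.rates, self.params, mask, scheme, "IHD")
        assert np.all(field.deaths == 0.0)

    def test_single_cell_reduces_to_cell_mortality(self):
        grid, mask, scheme = single_region_world()
        conc = ConcentrationField(grid=grid, values=np.array([[18.0]]))
        pop = PopulationGrid(grid=grid, counts=np.array([[[5e4]]]), age_groups=("70-74",))
        field = compute_endpoint(conc, pop, self.rates, self.params, mask, scheme, "LC")
        from pmhia.exposure_response import gemm_rr
        rr = gemm_rr(18.0, self.params.lookup(Endpoint.LC, "70-74"))
        expected = cell_mortality(self.rates.y0("Western", "LC", "70-74"), rr, 5e4)
        got = tuple(field.deaths[i, 0, 0, 0] for i in range(3))
        assert max_rel_err(expected, got) < 1e-12

    def test_sentinel_and_missing_cells_contribute_zero(self):
        grid = GridSpec.regular(45.0, 0.0, 1, 3, 0.5)
        mask = CountryMask(grid=grid, codes=np.array([["KW", "--", "KW"]], dtype=object))
        scheme = RegionScheme({"KW": Region.WESTERN})
        conc = ConcentrationField(grid=grid, values=np.array([[20.0, 20.0, np.nan]]))
        pop = PopulationGrid(grid=grid, counts=np.full((12, 1, 3), 1e4))
        field = compute_endpoint(conc, pop, self.rates, self.params, mask, scheme, "IHD")
        assert field.deaths[:, :, 0, 1].sum() == 0.0  # sentinel country
        assert field.deaths[:, :, 0, 2].sum() == 0.0  # missing concentration
        assert field.deaths[:, :, 0, 0].sum() > 0.0

    def test_grid_mismatch_rejected(self):
        grid, mask, scheme = single_region_world()
        other = GridSpec.regular(50.0, 0.0, 1, 1, 0.5)
        conc = ConcentrationField(grid=other, values=np.array([[10.0]]))
        pop = PopulationGrid(grid=grid, counts=np.ones((12, 1, 1)))
        with pytest.raises(GridError):
            compute_endpoint(conc, pop, self.rates, self.params, mask, scheme, "IHD")

    def test_linearity_in_population(self):
        grid, mask, scheme = single_region_world(2, 2)
        rng = np.random.default_rng(3)
        conc = ConcentrationField(grid=grid, values=rng.uniform(5, 30, (2, 2)))
        counts = rng.uniform(0, 1e5, (12, 2, 2))
        pop1 = PopulationGrid(grid=grid, counts=counts)
        pop2 = PopulationGrid(grid=grid, counts=2 * counts)
        f1 = compute_endpoint(conc, pop1, self.rates, self.params, mask, scheme, "CEV")
        f2 = compute_endpoint(conc, pop2, self.rates, self.params, mask, scheme, "CEV")
        np.testing.assert_allclose(f2.deaths, 2 * f1.deaths, rtol=1e-12)

    def test_monotone_in_concentration(self):
        grid, mask, scheme = single_region_world(1, 2)
        pop = PopulationGrid(grid=grid, counts=np.full((12, 1, 2), 1e4))
        lo = ConcentrationField(grid=grid, values=np.array([[10.0, 10.0]]))
        hi = ConcentrationField(grid=grid, values=np.array([[10.0, 15.0]]))
        f_lo = compute_endpoint(lo, pop, self.rates, self.params, mask, scheme, "IHD")
        f_hi = compute_endpoint(hi, pop, self.rates, self.params, mask, scheme, "IHD")
        assert np.all(f_hi.deaths >= f_lo.deaths - 1e-15)


class TestOtherNcd:
    def _fields(self, env_value, cause_value):
        grid, mask, scheme = single_region_world()
        def mk(endpoint, v):
            deaths = np.full((3, 1, 1, 1), v)
            return MortalityField(grid=grid, endpoint=endpoint, deaths=deaths, age_groups=("60-64",))
        env = mk(LABEL_ALL, env_value)
        causes = [mk(e.value, cause_value) for e in
                  (Endpoint.IHD, Endpoint.CEV, Endpoint.COPD, Endpoint.LC, Endpoint.LRI)]
        return env, causes

    def test_zero_causes_give_envelope(self):
        env, causes = self._fields(100.0, 0.0)
        other = derive_other_ncd(env, causes)
        np.testing.assert_array_equal(other.deaths, env.deaths)

    def test_exact_cancellation_gives_zero(self):
        env, causes = self._fields(100.0, 20.0)
        other = derive_other_ncd(env, causes)
        assert np.all(other.deaths == 0.0)

    def test_excess_causes_floored_at_zero(self, caplog):
        env, causes = self._fields(100.0, 20.0 + 1e-9)
        with caplog.at_level(logging.INFO, logger="pmhia.hia_engine"):
            other = derive_other_ncd(env, causes)
        assert np.all(other.deaths == 0.0)
        assert any("floored" in r.message for r in caplog.records)

    def test_mismatched_bands_rejected(self):
        env, causes = self._fields(100.0, 0.0)
        bad = MortalityField(
            grid=env.grid, endpoint="IHD",
            deaths=np.zeros((3, 2, 1, 1)), age_groups=("60-64", "80plus"),
        )
        with pytest.raises(ValidationError):
            derive_other_ncd(env, [bad] + causes[1:])


class TestAggregate:
    def test_printed_regional_totals_sum_to_europe(self):
        field, mask, scheme = regional_fixture_field(REGIONAL_ALL_CAUSE)
        summary = aggregate(field, mask, scheme)
        assert summary_value(summary, EUROPE, LABEL_ALL, ALL_AGE) == 904_000.0
        assert summary_value(summary, "Western", LABEL_ALL, ALL_AGE) == 166_000.0

    def test_one_region_domain_europe_equals_region(self):
        grid, mask, scheme = single_region_world(2, 2)
        deaths = np.random.default_rng(0).uniform(0, 10, (1, 1, 2, 2)).repeat(3, 0)
        field = MortalityField(grid=grid, endpoint="IHD", deaths=deaths, age_groups=("60-64",))
        summary = aggregate(field, mask, scheme)
        assert summary_value(summary, EUROPE, "IHD", ALL_AGE) == pytest.approx(
            summary_value(summary, "Western", "IHD", ALL_AGE), rel=1e-12
        )

    def test_random_field_sum_matches_summary(self, truth_bundle):
        rng = np.random.default_rng(9)
        b = truth_bundle
        deaths = np.sort(rng.uniform(0, 100, (3, 2, 1, 3)), axis=0)[[1, 0, 2]]
        field = MortalityField(
            grid=b.conc.grid, endpoint="IHD", deaths=deaths, age_groups=("60-64", "80plus")
        )
        summary = aggregate(field, b.mask, b.scheme)
        assert summary_value(summary, EUROPE, "IHD", ALL_AGE) == pytest.approx(
            float(deaths[0].sum()), rel=1e-9
        )


class TestPerArea:
    def test_hand_value(self):
        grid, mask, scheme = single_region_world()
        areas = cell_areas(grid)
        deaths = np.full((3, 1, 1, 1), 2.0 * areas.area[0, 0])
        field = MortalityField(grid=grid, endpoint="IHD", deaths=deaths, age_groups=("60-64",))
        assert per_area(field, areas)[0, 0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_zero_field_gives_zero_map(self):
        grid, mask, scheme = single_region_world(2, 2)
        field = MortalityField(
            grid=grid, endpoint="IHD", deaths=np.zeros((3, 1, 2, 2)), age_groups=("60-64",)
        )
        assert np.all(per_area(field, cell_areas(grid)) == 0.0)

    def test_inverse_operation_recovers_total(self):
        rng = np.random.default_rng(4)
        grid = GridSpec.regular(40.25, 0.25, 6, 6, 0.5)
        deaths = np.sort(rng.uniform(0, 50, (3, 2, 6, 6)), axis=0)[[1, 0, 2]]
        field = MortalityField(
            grid=grid, endpoint="IHD", deaths=deaths, age_groups=("60-64", "80plus")
        )
        areas = cell_areas(grid)
        recovered = (per_area(field, areas)[0] * areas.area).sum()
        assert recovered == pytest.approx(float(deaths[0].sum()), rel=1e-9)


class TestShares:
    def _summary_from_printed_totals(self):
        """Table-style fixture: EUROPE endpoint totals in deaths."""
        totals = {
            "CEV": 90_000.0, "IHD": 435_000.0, "COPD": 29_000.0, "LC": 46_000.0,
            "LRI": 41_000.0, LABEL_OTHER: 263_000.0, LABEL_ALL: 904_000.0,
        }
        frames = []
        for endpoint, value in totals.items():
            field, mask, scheme = regional_fixture_field(
                {"Western": value, "Central": 0.0, "Eastern": 0.0}
            )
            field = MortalityField(
                grid=field.grid, endpoint=endpoint, deaths=field.deaths,
                age_groups=field.age_groups,
            )
            frames.append(aggregate(field, mask, scheme))
        return pd.concat(frames, ignore_index=True)

    def test_printed_percentages(self):
        summary = self._summary_from_printed_totals()
        table = shares(summary).set_index("endpoint")
        assert table.loc["IHD", "share_percent_rounded"] == 48
        assert table.loc[LABEL_OTHER, "share_percent_rounded"] == 29
        assert table.loc["COPD", "share_percent_rounded"] == 3
        combined = table.loc["IHD", "share_percent"] + table.loc["CEV", "share_percent"]
        assert round_half_away(combined) == 58

    def test_single_nonzero_endpoint_is_100(self):
        field, mask, scheme = regional_fixture_field(
            {"Western": 10.0, "Central": 0.0, "Eastern": 0.0}
        )
        summary = aggregate(field, mask, scheme)
        table = shares(summary).set_index("endpoint")
        assert table.loc[LABEL_ALL, "share_percent"] == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        field, mask, scheme = regional_fixture_field(
            {"Western": 0.0, "Central": 0.0, "Eastern": 0.0}
        )
        with pytest.raises(ValidationError):
            shares(aggregate(field, mask, scheme))


class TestKnownTruthRecovery:
    def test_every_summary_row_matches_scalar_oracle(self, truth_bundle):
        b = truth_bundle
        fields = compute_all_endpoints(b.conc, b.pop, b.rates, b.params, b.mask, b.scheme)
        got = pd.concat(
            [aggregate(f, b.mask, b.scheme) for f in fields.values()], ignore_index=True
        )
        merged = b.expected.merge(
            got, on=["region", "endpoint", "age_group"], suffixes=("_e", "_g")
        )
        assert len(merged) == len(b.expected)
        for col in ("central", "low", "high"):
            assert max_rel_err(merged[f"{col}_e"], merged[f"{col}_g"]) < 1e-12

    def test_counterfactual_cell_contributes_nothing(self, truth_bundle):
        b = truth_bundle  # middle (Central) cell sits exactly at zcf
        fields = compute_all_endpoints(b.conc, b.pop, b.rates, b.params, b.mask, b.scheme)
        for f in fields.values():
            assert f.deaths[:, :, 0, 1].sum() == 0.0

    def test_endpoint_additivity_without_flooring(self, truth_bundle):
        b = truth_bundle
        fields = compute_all_endpoints(b.conc, b.pop, b.rates, b.params, b.mask, b.scheme)
        causes = sum(fields[e.value].deaths[0] for e in
                     (Endpoint.IHD, Endpoint.CEV, Endpoint.COPD, Endpoint.LC, Endpoint.LRI))
        reconstructed = causes + fields[LABEL_OTHER].deaths[0]
        envelope = fields[LABEL_ALL].deaths[0]
        if np.all(envelope - causes >= 0):  # no flooring occurred
            np.testing.assert_allclose(reconstructed, envelope, rtol=1e-12)


def test_round_half_away():
    assert round_half_away(72.57) == 73
    assert round_half_away(0.5) == 1
    assert round_half_away(-0.5) == -1
    assert round_half_away(2.4) == 2
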