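"""DDD exposure, era growth, market share and the reinvestment counterfactual."""

import pytest

from tnfi_bia import (
    AnnualDrugRecord,
    MissingYearError,
    RecordValidationError,
    Sector,
    cost_series_from_values,
    ddd_series,
    eligible_coverage,
    era_growth,
    market_share,
    per_patient_cost_series,
    potential_additional_patients,
    real_life_savings,
    subset,
)
from tnfi_bia.costs import CostMethod
from tnfi_bia.records import patients_by_year
from tnfi_bia.synth import (MarketScenarioConfig, biosimilar_share,
                            generate_series, product_spend)

M = 1e6


class TestDDD:
    @pytest.mark.parametrize("drug,year,ref,expected_ddd", [
        ("INF", 2013, 2013, 255_657),    # 958 714 mg / 3.75 mg
        ("INF", 2018, 2013, 1_068_464),
        ("ADA", 2018, 2018, 1_139_596),  # 3 304 828 mg / 2.9 mg
        ("ETN", 2015, 2015, 613_835),
        ("ETN", 2021, 2015, 945_957),
    ])
    def test_published_ddd_counts(self, poland, drug, year, ref, expected_ddd):
        """Published dose counts are the volume/DDD ratio to the nearest whole
        dose (one published adalimumab cell sits a single dose off)."""
        ds = ddd_series(subset(poland, drug, "ALL"), poland.meta[drug].ddd_mg,
                        poland.population, ref)
        assert round(ds.per_year[year].n_ddd) == expected_ddd

    def test_rate_per_1000_inhabitants(self, poland):
        ds = ddd_series(subset(poland, "INF", "ALL"), 3.75, poland.population, 2013)
        assert ds.per_year[2013].ddd_per_1000_per_year == pytest.approx(6.73, abs=0.01)
        assert ds.per_year[2021].ddd_per_1000_per_year == pytest.approx(30.12, abs=0.01)

    def test_etn_2021_exposure_154_pct_of_reference(self, poland):
        ds = ddd_series(subset(poland, "ETN", "ALL"), 7.0, poland.population, 2015)
        assert round(ds.per_year[2021].pct_of_reference) == 154

    def test_zero_volume_gives_zero_ddd(self):
        series = [AnnualDrugRecord("X", 2013, Sector.ALL, 0.0, 0.0, 0)]
        ds = ddd_series(series, 3.75, 1e6, 2013)
        assert ds.per_year[2013].n_ddd == 0.0
        assert ds.per_year[2013].ddd_per_1000_per_year == 0.0

    def test_invalid_inputs_rejected(self, poland):
        series = subset(poland, "INF", "ALL")
        with pytest.raises(RecordValidationError):
            ddd_series(series, 0.0, poland.population, 2013)
        with pytest.raises(RecordValidationError):
            ddd_series(series, 3.75, 0.0, 2013)


class TestReinvestment:
    def test_ada_2019_additional_patients(self, poland):
        """19.623M of savings at the 2019 per-patient cost funds 9772 more."""
        series = subset(poland, "ADA", "ALL")
        report = potential_additional_patients(
            real_life_savings(series, 2018),
            per_patient_cost_series(series, 2018), series)
        assert report.per_year[2019].potential_additional == 9772
        assert report.per_year[2019].total_potential == 5706 + 9772

    def test_etn_2016_additional_patients(self, poland):
        series = subset(poland, "ETN", "ALL")
        report = potential_additional_patients(
            real_life_savings(series, 2015),
            per_patient_cost_series(series, 2015), series)
        assert report.per_year[2016].potential_additional == 206

    def test_zero_savings_zero_additional(self):
        series = [AnnualDrugRecord("X", y, Sector.ALL, 100.0, 500.0, 5)
                  for y in (2013, 2014)]
        report = potential_additional_patients(
            real_life_savings(series, 2013),
            per_patient_cost_series(series, 2013), series)
        assert report.per_year[2014].potential_additional == 0

    def test_negative_savings_clamped_to_zero(self):
        series = [AnnualDrugRecord("X", 2013, Sector.ALL, 100.0, 500.0, 5),
                  AnnualDrugRecord("X", 2014, Sector.ALL, 100.0, 900.0, 5)]
        report = potential_additional_patients(
            real_life_savings(series, 2013),
            per_patient_cost_series(series, 2013), series)
        assert report.per_year[2014].potential_additional == 0

    def test_antitone_in_cost_monotone_in_savings(self, poland):
        """More expensive treatment funds fewer patients; more savings more."""
        series = subset(poland, "ADA", "ALL")
        sav = real_life_savings(series, 2018)
        base = per_patient_cost_series(series, 2018)
        doubled = cost_series_from_values(
            "ADA", "ALL", CostMethod.PER_PATIENT, 2018,
            {y: 2 * c.cost for y, c in base.per_year.items()})
        more = potential_additional_patients(sav, base, series)
        fewer = potential_additional_patients(sav, doubled, series)
        for y in (2019, 2020, 2021):
            assert fewer.per_year[y].potential_additional <= \
                more.per_year[y].potential_additional

    PUBLISHED_ALL = {  # potential additional patients, combined sector
        "INF": {2019: 1234, 2020: 4092, 2021: 5549},
        "ETN": {2016: 206, 2017: 978, 2018: 2214, 2019: 3760, 2020: 5337,
                2021: 5787},
        "ADA": {2019: 9772, 2020: 24606, 2021: 35009},
    }

    def test_reconstructs_every_published_combined_sector_cell(
            self, poland, reported_costs):
        """Real-life savings reinvested at the payer's published per-patient
        cost reproduce the published counterfactual within rounding slack
        (+-2 patients or 0.5%, whichever is larger)."""
        refs = {"INF": 2018, "ETN": 2015, "ADA": 2018}
        for drug, cells in self.PUBLISHED_ALL.items():
            series = subset(poland, drug, "ALL")
            cost = cost_series_from_values(
                drug, "ALL", CostMethod.PER_PATIENT, refs[drug],
                reported_costs[drug]["per_patient"])
            report = potential_additional_patients(
                real_life_savings(series, refs[drug]), cost, series)
            for year, expected in cells.items():
                got = report.per_year[year].potential_additional
                slack = max(2, 0.005 * expected)
                assert abs(got - expected) <= slack, (drug, year, got, expected)


class TestEraGrowth:
    def test_inf_rmd_trajectory(self, poland):
        g = era_growth(subset(poland, "INF", "RMD"), (2013, 2021))
        assert g.absolute == 216
        assert g.relative == pytest.approx(204, abs=1)  # "approximately 200%"

    def test_etn_rmd_since_market_exclusivity(self, poland):
        g = era_growth(subset(poland, "ETN", "RMD"), (2015, 2021))
        assert g.absolute == 955

    def test_degenerate_era(self, poland):
        g = era_growth(subset(poland, "INF", "RMD"), (2015, 2015))
        assert (g.absolute, g.relative) == (0, 0.0)

    def test_missing_endpoint_is_error(self, poland):
        with pytest.raises(MissingYearError):
            era_growth(subset(poland, "ETN", "RMD"), (2010, 2015))


class TestMarketShare:
    def test_reference_only(self, poland):
        shares = market_share({("Remicade", 2013): 4.6e6}, poland.meta["INF"])
        assert shares[2013] == (100.0, 0.0)

    def test_even_split(self, poland):
        shares = market_share({("Remicade", 2020): 5e5, ("Remsima", 2020): 5e5},
                              poland.meta["INF"])
        assert shares[2020] == (50.0, 50.0)

    def test_unflagged_product_rejected(self, poland):
        with pytest.raises(RecordValidationError, match="Mystery"):
            market_share({("Mystery", 2020): 1.0}, poland.meta["INF"])

    def test_synthetic_takeover_path_recovered(self):
        """Shares computed from generated product-level spend follow the
        configured takeover path exactly when noise is off."""
        cfg = MarketScenarioConfig(noise_cv=0.0, share_takeover=0.3,
                                   entry_year=2019, years=(2017, 2021))
        rs = generate_series(cfg)
        shares = market_share(product_spend(cfg, rs), rs.meta[cfg.drug])
        for year, (_, bio_pct) in shares.items():
            assert bio_pct == pytest.approx(100 * biosimilar_share(cfg, year))


class TestEligibleCoverage:
    def test_conservative_threshold_band(self):
        """~45k treatable patients over a 550k inflammatory-arthritis
        population covers 14-20% of the biologic-eligible pool."""
        assert eligible_coverage(44_663, 550_000, 0.40) == pytest.approx(20.3, abs=0.05)
        assert eligible_coverage(44_663, 550_000, 0.60) == pytest.approx(13.5, abs=0.05)

    def test_total_potential_matches_published_sum(self, bundle):
        """The 2021 RMD total-potential counts sum to almost 45 000."""
        total = sum(bundle.access["RMD"][d].per_year[2021].total_potential
                    for d in ("INF", "ETN", "ADA"))
        assert total == pytest.approx(44_663, rel=0.005)
        assert eligible_coverage(total, 550_000, 0.40) == pytest.approx(20, abs=0.5)

    def test_full_coverage(self):
        assert eligible_coverage(1000, 1000, 1.0) == pytest.approx(100.0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(RecordValidationError):
            eligible_coverage(10, 100, 0.0)


def test_patients_by_year_skips_missing():
    series = [AnnualDrugRecord("X", 2013, Sector.ALL, 1.0, 1.0, 5),
              AnnualDrugRecord("X", 2014, Sector.ALL, 1.0, 1.0, None)]
    assert patients_by_year(series) == {2013: 5}
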