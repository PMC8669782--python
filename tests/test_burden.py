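"""Comparative risk assessment: interpolation, PAFs, burden accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cvburden as cb
from cvburden.burden import interpolate_log_rr


def _rr_table(log_rrs, ses=None, bands=("35-44", "45-54", "55-64", "65-74", "75-84", "85+")):
    n = len(log_rrs)
    return pd.DataFrame(
        {
            "risk_factor": "sbp",
            "band": list(bands)[:n],
            "log_rr": log_rrs,
            "se": ses if ses is not None else [0.01] * n,
        }
    )


class TestInterpolation:
    def test_constant_input_constant_output(self):
        out = cb.interpolate_rr_5y(_rr_table([0.3] * 6))
        assert np.allclose(out["log_rr"], 0.3)
        assert list(out["age_group"]) == list(cb.FIVE_YEAR_GROUPS)

    def test_linear_midpoint_halfway(self):
        tab = _rr_table([0.6, 0.4], bands=("35-44", "45-54"))
        assert interpolate_log_rr(tab, [45.0]) == pytest.approx(0.5)

    def test_ten_year_midpoints_are_fixed_points(self):
        vals = [0.5, 0.4, 0.35, 0.25, 0.15, 0.1]
        tab = _rr_table(vals)
        mids = [40.0, 50.0, 60.0, 70.0, 80.0, 90.0]
        assert np.allclose(interpolate_log_rr(tab, mids), vals)

    def test_flat_extrapolation_below_youngest_band(self):
        out = cb.interpolate_rr_5y(_rr_table([0.5, 0.4], bands=("35-44", "45-54")))
        young = out.loc[out["age_group"].isin(["20-24", "30-34"]), "log_rr"]
        assert np.allclose(young, 0.5)

    def test_single_band_constant_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            out = cb.interpolate_rr_5y(_rr_table([0.3], bands=("45-54",)))
        assert np.allclose(out["log_rr"], 0.3)

    def test_se_interpolated_alongside(self):
        out = cb.interpolate_rr_5y(_rr_table([0.6, 0.4], [0.02, 0.04], bands=("35-44", "45-54")))
        row = out.set_index("age_group").loc["40-44"]
        # group midpoint 42.5 sits a quarter of the way from 40 to 50
        assert row["se"] == pytest.approx(0.02 + 0.25 * 0.02)


class TestPaf:
    def test_no_excess_exposure_gives_zero(self):
        assert cb.paf(0.02, 110.0, 115.0) == 0.0
        assert cb.paf(0.02, 115.0, 115.0) == 0.0

    def test_doubling_risk_gives_half(self):
        # exp(log_rr * delta) = 2 -> paf = 0.5
        delta = np.log(2) / 0.02
        assert cb.paf(0.02, 115.0 + delta, 115.0) == pytest.approx(0.5)

    def test_closed_form_matches_quadrature(self):
        closed = cb.paf(0.02, 135.0, 115.0)
        numeric = cb.paf_numeric(0.02, 135.0, 15.0, 115.0)
        assert closed == pytest.approx(numeric, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(
        log_rr=st.floats(1e-4, 0.3),
        delta=st.floats(0.0, 40.0),
    )
    def test_bounds_and_monotonicity(self, log_rr, delta):
        p = cb.paf(log_rr, 115.0 + delta, 115.0)
        assert 0.0 <= p < 1.0
        assert cb.paf(log_rr * 1.1, 115.0 + delta, 115.0) >= p
        assert cb.paf(log_rr, 115.0 + delta + 1.0, 115.0) > p


def _paf_cells():
    rows = []
    rng = np.random.default_rng(8)
    for country in ("A", "B", "C"):
        for sex in ("female", "male"):
            for grp in cb.FIVE_YEAR_GROUPS:
                rows.append((country, sex, grp, "sbp", rng.uniform(0.05, 0.5)))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "risk_factor", "paf"])


def _deaths_cells():
    rows = []
    rng = np.random.default_rng(9)
    for country in ("A", "B", "C"):
        for sex in ("female", "male"):
            for grp in cb.FIVE_YEAR_GROUPS:
                rows.append((country, sex, grp, int(rng.integers(10, 500)), float(rng.uniform(1e4, 1e6))))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "deaths", "population"])


class TestAttributableDeaths:
    def test_zero_paf_zero_deaths(self):
        paf = _paf_cells().assign(paf=0.0)
        out = cb.attributable_deaths(paf, _deaths_cells())
        assert (out["attributable"] == 0).all()

    def test_product_per_stratum(self):
        paf = _paf_cells()
        out = cb.attributable_deaths(paf, _deaths_cells())
        assert np.allclose(out["attributable"], out["paf"] * out["deaths"])
        assert (out["attributable"] <= out["deaths"]).all()

    def test_missing_stratum_is_hard_error(self):
        paf = _paf_cells().iloc[:-1]
        with pytest.raises(ValueError, match="strata"):
            cb.attributable_deaths(paf, _deaths_cells())

    def test_totals_conserve_across_aggregation_levels(self):
        out = cb.attributable_deaths(_paf_cells(), _deaths_cells())
        by_country = out.groupby("country")["attributable"].sum()
        total = out["attributable"].sum()
        assert by_country.sum() == pytest.approx(total)
        submap = {"A": "R1", "B": "R1", "C": "R2"}
        country_tab = (
            out.groupby(["country", "sex", "risk_factor"])[["attributable"]]
            .sum()
            .reset_index()
            .assign(population=1e6)
        )
        agg = cb.aggregate_subregion(country_tab, submap)
        assert agg["attributable"].sum() == pytest.approx(total)


class TestRatesAndRatios:
    def test_crude_rate_arithmetic(self):
        assert cb.crude_attrib_rate(500.0, 1_000_000.0) == pytest.approx(50.0)
        assert cb.crude_attrib_rate(0.0, 1e6) == 0.0
        assert cb.crude_attrib_rate(5000.0, 1e7) == cb.crude_attrib_rate(500.0, 1e6)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            cb.crude_attrib_rate(10.0, 0.0)

    def test_premature_ratio_published_examples(self):
        assert cb.premature_ratio(2659, 3299) == pytest.approx(80.60, abs=0.02)
        assert cb.premature_ratio(6072, 13590) == pytest.approx(44.68, abs=0.02)

    def test_all_premature_is_100(self):
        assert cb.premature_ratio(120.0, 120.0) == pytest.approx(100.0)

    def test_zero_denominator_undefined(self):
        assert np.isnan(cb.premature_ratio(0.0, 0.0))

    def test_ratio_table_splits_at_70(self):
        cells = cb.attributable_deaths(_paf_cells(), _deaths_cells())
        tab = cb.premature_ratio_table(cells)
        young = cells.loc[cells["age_group"].map(lambda g: int(g.rstrip("+").split("-")[0])) < 70]
        expected = young["attributable"].sum() / cells["attributable"].sum() * 100
        overall = 100 * tab["premature"].sum() / tab["all_ages"].sum()
        assert overall == pytest.approx(expected)
        assert ((tab["ratio_pct"] >= 0) & (tab["ratio_pct"] <= 100)).all()


class TestAggregateSubregion:
    def test_single_country_subregion_is_identity(self):
        tab = pd.DataFrame(
            {"country": ["A"], "attributable": [250.0], "population": [1e6]}
        )
        agg = cb.aggregate_subregion(tab, {"A": "R"})
        assert agg.iloc[0]["rate_per_100k"] == pytest.approx(25.0)

    def test_population_weighted_mean(self):
        tab = pd.DataFrame(
            {
                "country": ["A", "B"],
                "attributable": [10.0 / 1e5 * 3e6, 30.0 / 1e5 * 1e6],
                "population": [3e6, 1e6],
            }
        )
        agg = cb.aggregate_subregion(tab, {"A": "R", "B": "R"})
        assert agg.iloc[0]["rate_per_100k"] == pytest.approx(15.0)

    def test_unmapped_country_is_error(self):
        tab = pd.DataFrame({"country": ["A"], "attributable": [1.0], "population": [1.0]})
        with pytest.raises(ValueError, match="map"):
            cb.aggregate_subregion(tab, {})


class TestMonteCarlo:
    def _inputs(self, se=0.01):
        rr5 = cb.interpolate_rr_5y(_rr_table([0.03, 0.025, 0.02, 0.015, 0.01, 0.007],
                                             [se] * 6))
        exp = cb.synthetic_exposure_surface(["A", "B"], seed=3)
        exp = exp.loc[exp["risk_factor"] == "sbp"].reset_index(drop=True)
        deaths = cb.synthetic_mortality_table(["A", "B"], seed=3)
        return rr5, exp, deaths

    def test_zero_se_collapses_to_point(self):
        rr5, exp, deaths = self._inputs(se=0.0)
        out = cb.monte_carlo_ci(rr5, exp, deaths, n_draws=50, seed=1)["country"]
        assert np.allclose(out["all_ages_low"], out["all_ages"])
        assert np.allclose(out["all_ages_high"], out["all_ages"])

    def test_same_seed_same_intervals(self):
        rr5, exp, deaths = self._inputs()
        a = cb.monte_carlo_ci(rr5, exp, deaths, n_draws=100, seed=5)["country"]
        b = cb.monte_carlo_ci(rr5, exp, deaths, n_draws=100, seed=5)["country"]
        pd.testing.assert_frame_equal(a, b)

    def test_interval_widens_with_se(self):
        widths = []
        for se in (0.002, 0.01, 0.05):
            rr5, exp, deaths = self._inputs(se=se)
            out = cb.monte_carlo_ci(rr5, exp, deaths, n_draws=300, seed=2)["country"]
            widths.append((out["all_ages_high"] - out["all_ages_low"]).mean())
        assert widths[0] < widths[1] < widths[2]

    def test_point_inside_interval_and_subregion_conserves(self):
        rr5, exp, deaths = self._inputs()
        out = cb.monte_carlo_ci(
            rr5, exp, deaths, n_draws=300, seed=4, subregion_map={"A": "R", "B": "R"}
        )
        c = out["country"]
        assert ((c["all_ages_low"] <= c["all_ages"]) & (c["all_ages"] <= c["all_ages_high"])).all()
        s = out["subregion"]
        for (sex, rf), grp in c.groupby(["sex", "risk_factor"]):
            row = s.loc[(s["sex"] == sex) & (s["risk_factor"] == rf)].iloc[0]
            assert row["all_ages"] == pytest.approx(grp["all_ages"].sum())
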