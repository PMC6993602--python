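"""Preprocessing: weekly averaging, imputation, standardization, sequences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yieldnet.preprocess import (
    N_DEPTHS,
    N_MGMT_WEEKS,
    N_SOIL_VARS,
    CountyYearRecord,
    DimensionError,
    EmptyDatasetError,
    ImputationError,
    ManagementSeries,
    SoilProfile,
    WeatherSeries,
    build_sequences,
    impute_management,
    impute_soil,
    standardize,
    weekly_average,
    yearly_average_yield,
)


def make_record(county="A", state="S0", year=2000, yield_value=100.0):
    return CountyYearRecord(
        county_id=county,
        state_id=state,
        year=year,
        weather=WeatherSeries(np.zeros((6, 52))),
        soil=SoilProfile(np.ones((10, 9)), np.ones(4)),
        management=ManagementSeries(np.linspace(0, 100, 16)),
        yield_value=yield_value,
    )


class TestWeeklyAverage:
    def test_constant_series_maps_to_constant_weeks(self):
        out = weekly_average(np.full(365, 3.0))
        assert out.shape == (52,)
        assert np.allclose(out, 3.0)

    def test_any_series_reduces_to_52_values(self):
        out = weekly_average(np.random.default_rng(0).normal(size=365))
        assert out.shape == (52,)

    @pytest.mark.parametrize("n", [365, 366])
    def test_block_means_match_independent_oracle(self, n):
        daily = np.random.default_rng(5).normal(size=n)
        out = weekly_average(daily)
        # independent oracle: explicit block means, last week absorbs the tail
        for j in range(51):
            assert out[j] == pytest.approx(daily[7 * j : 7 * (j + 1)].mean())
        assert out[51] == pytest.approx(daily[357:].mean())

    def test_mean_preserving_on_block_constant_input(self):
        blocks = np.repeat(np.arange(52.0), 7)
        daily = np.concatenate([blocks, [51.0]])  # day 365 joins week 52
        assert np.allclose(weekly_average(daily), np.arange(52.0))

    def test_sum_identity_on_364_day_prefix(self):
        daily = np.random.default_rng(9).normal(size=365)
        out = weekly_average(daily)
        assert out[:51].sum() * 7 == pytest.approx(daily[:357].sum())

    @pytest.mark.parametrize("n", [0, 100, 364, 367])
    def test_wrong_length_raises(self, n):
        with pytest.raises(DimensionError):
            weekly_average(np.zeros(n))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=365, max_size=366
        )
    )
    def test_block_mean_property_for_arbitrary_series(self, values):
        daily = np.array(values)
        out = weekly_average(daily)
        assert out.shape == (52,)
        for j in range(51):
            assert out[j] == pytest.approx(daily[7 * j : 7 * j + 7].mean())
        assert out[51] == pytest.approx(daily[357:].mean())


class TestImputeSoil:
    def test_no_missing_is_identity(self):
        records = [make_record(c) for c in "ABC"]
        out = impute_soil(records)
        for a, b in zip(records, out):
            assert np.array_equal(a.soil.depth_values, b.soil.depth_values)

    def test_missing_value_gets_cross_county_mean(self):
        records = [make_record(c) for c in "ABCD"]
        for r, v in zip(records[:3], (1.0, 2.0, 3.0)):
            r.soil.depth_values[2, 4] = v
        records[3].soil.depth_values[2, 4] = np.nan
        out = impute_soil(records)
        assert out[3].soil.depth_values[2, 4] == pytest.approx(2.0)

    def test_surface_missing_imputed_too(self):
        records = [make_record(c) for c in "AB"]
        records[0].soil.surface_values[1] = 5.0
        records[1].soil.surface_values[1] = np.nan
        out = impute_soil(records)
        assert out[1].soil.surface_values[1] == pytest.approx(5.0)

    def test_feature_missing_everywhere_raises_named_error(self):
        records = [make_record(c) for c in "AB"]
        for r in records:
            r.soil.depth_values[0, 0] = np.nan
        with pytest.raises(ImputationError, match="wet_bulk_density@0-5cm"):
            impute_soil(records)

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(3)
        records = [make_record(c) for c in "ABCDE"]
        originals = []
        for r in records:
            r.soil.depth_values = rng.normal(size=(N_SOIL_VARS, N_DEPTHS))
            mask = rng.random((N_SOIL_VARS, N_DEPTHS)) < 0.2
            r.soil.depth_values[mask] = np.nan
            originals.append(r.soil.depth_values.copy())
        out = impute_soil(records)
        for orig, r in zip(originals, out):
            obs = ~np.isnan(orig)
            assert np.array_equal(orig[obs], r.soil.depth_values[obs])
            assert not np.isnan(r.soil.depth_values).any()


class TestImputeManagement:
    def test_no_missing_is_identity(self):
        records = [make_record(c) for c in "AB"]
        out = impute_management(records)
        for a, b in zip(records, out):
            assert np.array_equal(
                a.management.cumulative_planted, b.management.cumulative_planted
            )

    def test_group_mean_within_same_year(self):
        a = make_record("A", year=2000)
        b = make_record("B", year=2000)
        c = make_record("C", year=2000)
        a.management.cumulative_planted = np.linspace(0.0, 20.0, N_MGMT_WEEKS)
        b.management.cumulative_planted[9] = 20.0
        c.management.cumulative_planted[9] = 40.0
        a.management.cumulative_planted[9] = np.nan
        out = impute_management([a, b, c])
        assert out[0].management.cumulative_planted[9] == pytest.approx(30.0)

    def test_other_years_do_not_leak(self):
        a = make_record("A", year=2000)
        a.management.cumulative_planted[9] = np.nan
        b = make_record("B", year=2001)  # observed, but wrong year
        with pytest.raises(ImputationError, match="year 2000"):
            impute_management([a, b])

    def test_imputed_series_is_reclipped_monotone(self):
        a = make_record("A", year=2000)
        b = make_record("B", year=2000)
        a.management.cumulative_planted = np.linspace(0, 100, N_MGMT_WEEKS)
        a.management.cumulative_planted[5] = np.nan
        b.management.cumulative_planted = np.full(N_MGMT_WEEKS, 1.0)
        out = impute_management([a, b])
        series = out[0].management.cumulative_planted
        assert np.all(np.diff(series) >= 0)
        assert series.min() >= 0 and series.max() <= 100


class TestStandardize:
    def test_two_point_feature_maps_to_plus_minus_one(self):
        a, b = make_record("A"), make_record("B")
        a.soil.depth_values[0, 0] = 2.0
        b.soil.depth_values[0, 0] = 4.0
        out, _ = standardize([a, b])
        assert out[0].soil.depth_values[0, 0] == pytest.approx(-1.0)
        assert out[1].soil.depth_values[0, 0] == pytest.approx(1.0)

    def test_constant_feature_maps_to_zero(self):
        out, _ = standardize([make_record("A"), make_record("B")])
        assert np.allclose(out[0].weather.values, 0.0)

    def test_validation_records_use_training_stats(self):
        a, b = make_record("A"), make_record("B")
        a.soil.depth_values[0, 0] = 2.0
        b.soil.depth_values[0, 0] = 4.0
        _, stats = standardize([a, b])
        v = make_record("V")
        v.soil.depth_values[0, 0] = 5.0  # own stats would give 0
        out, _ = standardize([v], stats)
        assert out[0].soil.depth_values[0, 0] == pytest.approx(2.0)  # (5-3)/1


class TestBuildSequences:
    @staticmethod
    def county_years(county, years, yields=None):
        return [
            make_record(
                county,
                year=y,
                yield_value=(yields[i] if yields else 100.0 + i),
            )
            for i, y in enumerate(years)
        ]

    def test_full_window_yields_one_sample(self):
        records = self.county_years("A", range(1980, 1986))
        samples = build_sequences(records, k=5, target_years={1985})
        assert len(samples) == 1
        assert samples[0].target_year == 1985
        assert samples[0].weather.shape == (5, 6, 52)

    def test_missing_year_breaks_the_window(self):
        records = self.county_years("A", [1980, 1981, 1982, 1984, 1985])
        with pytest.raises(EmptyDatasetError):
            build_sequences(records, k=5, target_years={1985})

    def test_avg_yield_is_cross_county_mean(self):
        a = self.county_years("A", [2000, 2001], yields=[100.0, 120.0])
        b = self.county_years("B", [2000, 2001], yields=[110.0, 100.0])
        samples = build_sequences(a + b, k=2, target_years={2001})
        assert len(samples) == 2
        assert np.allclose(samples[0].avg_yield, [105.0, 110.0])

    def test_count_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        records = []
        present = {}
        for county in "ABCD":
            years = sorted(
                rng.choice(range(2000, 2010), size=rng.integers(4, 9), replace=False)
            )
            present[county] = set(int(y) for y in years)
            records += self.county_years(county, [int(y) for y in years])
        k = 3
        samples = build_sequences(records, k=k)
        expected = sum(
            all(t - j in years for j in range(k))
            for county, years in present.items()
            for t in years
        )
        assert len(samples) == expected

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_sequences([make_record()], k=0)


def test_processed_container_roundtrip(tmp_path):
    from yieldnet.preprocess import load_processed, save_processed

    records = [make_record(c, year=2000 + i) for i, c in enumerate("ABC")]
    records[1].soil.depth_values[2, 2] = np.nan  # NaN survives the roundtrip
    path = tmp_path / "processed.npz"
    save_processed(records, path)
    back = load_processed(path)
    assert len(back) == 3
    for a, b in zip(records, back):
        assert (a.county_id, a.state_id, a.year) == (b.county_id, b.state_id, b.year)
        assert np.array_equal(a.weather.values, b.weather.values)
        assert np.array_equal(
            a.soil.depth_values, b.soil.depth_values, equal_nan=True
        )


def test_yearly_average_ignores_missing_yields():
    a = make_record("A", year=2000, yield_value=100.0)
    b = make_record("B", year=2000, yield_value=float("nan"))
    assert yearly_average_yield([a, b]) == {2000: 100.0}
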