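"""Metrics, baselines, ablations, location CV, weather-update experiment."""

import numpy as np
import pytest

from yieldnet.experiments import (
    DFNN,
    average_baseline,
    baseline_lasso,
    baseline_rf,
    evaluate,
    evaluate_average_baseline,
    location_folds,
    weather_update_experiment,
)
from yieldnet.model import ModelConfig, count_parameters, parameter_shapes, samples_to_batch
from yieldnet.preprocess import CountyYearRecord, ManagementSeries, SoilProfile, WeatherSeries
from yieldnet.training import predict


def make_record(county, year, yield_value):
    return CountyYearRecord(
        county_id=county,
        state_id="S0",
        year=year,
        weather=WeatherSeries(np.zeros((6, 52))),
        soil=SoilProfile(np.zeros((10, 9)), np.zeros(4)),
        management=ManagementSeries(np.zeros(16)),
        yield_value=yield_value,
    )


class TestEvaluate:
    def test_perfect_prediction(self):
        rmse, corr = evaluate(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert rmse == 0.0
        assert corr == pytest.approx(100.0)

    def test_constant_predictor_reports_zero_correlation(self):
        rmse, corr = evaluate(np.full(5, 7.0), np.arange(5.0))
        assert corr == 0.0

    def test_hand_formula_example(self):
        pred, truth = np.array([1.0, 2, 3]), np.array([2.0, 2, 5])
        rmse, corr = evaluate(pred, truth)
        assert rmse == pytest.approx(np.sqrt((1 + 0 + 4) / 3))
        expected_corr = 100 * np.cov(pred, truth, bias=True)[0, 1] / (
            pred.std() * truth.std()
        )
        assert corr == pytest.approx(expected_corr)

    def test_matches_independent_single_pass_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p, t = rng.normal(size=30), rng.normal(size=30)
            rmse, corr = evaluate(p, t)
            # independent single-pass accumulation
            n = len(p)
            sp, st, spp, stt, spt, sse = 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
            for a, b in zip(p, t):
                sp += a; st += b; spp += a * a; stt += b * b; spt += a * b
                sse += (a - b) ** 2
            r = (n * spt - sp * st) / np.sqrt(
                (n * spp - sp**2) * (n * stt - st**2)
            )
            assert rmse == pytest.approx(np.sqrt(sse / n), abs=1e-10)
            assert corr == pytest.approx(100 * r, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), np.zeros(4))


class TestAverageBaseline:
    def test_single_county_prior_year(self):
        records = [make_record("A", 1999, 100.0), make_record("A", 2000, 120.0)]
        assert average_baseline(records, 2000) == 100.0

    def test_three_county_hand_mean(self):
        records = [
            make_record(c, 2009, v) for c, v in zip("ABC", (90.0, 100.0, 110.0))
        ] + [make_record(c, 2010, 1.0) for c in "ABC"]
        assert average_baseline(records, 2010) == pytest.approx(100.0)

    def test_correlation_is_zero_by_constancy(self, sim_records, split):
        records, _ = sim_records
        report = evaluate_average_baseline(records, split.val_samples)
        assert report.val_corr_pct == 0.0
        assert report.val_rmse > 0


class TestAblation:
    def test_weather_variant_drops_soil_and_management_parameters(self):
        config = ModelConfig.small().variant("W")
        names = set(parameter_shapes(config))
        assert not any(n.startswith(("scnn", "sfc")) for n in names)
        assert any(n.startswith("wcnn") for n in names)
        # step input shrinks: no soil FC, surface bypass or management weeks
        full = ModelConfig.small()
        assert config.step_input_size == full.step_input_size - (
            full.fc_soil_units + 4 + full.n_mgmt_weeks
        )

    def test_variant_parameter_count_is_smaller(self):
        from yieldnet.training import init_params

        full = count_parameters(init_params(ModelConfig.small(), 0))
        w_only = count_parameters(init_params(ModelConfig.small().variant("W"), 0))
        m_only = count_parameters(init_params(ModelConfig.small().variant("M"), 0))
        assert m_only < w_only < full


class TestBaselines:
    def test_lasso_with_huge_penalty_predicts_target_mean(self, split):
        from yieldnet.experiments import flatten_features
        from sklearn.linear_model import Lasso

        Xtr, ytr = flatten_features(split.train_samples)
        model = Lasso(alpha=1e9, max_iter=20000).fit(Xtr, ytr)
        # all non-intercept coefficients shrink to zero: mean predictor
        assert np.allclose(model.coef_, 0.0)
        assert np.allclose(model.predict(Xtr), ytr.mean())

    def test_rf_fits_noise_free_step_function(self, split):
        # tree-expressiveness sanity: overwrite targets with a step function
        # of one feature and check near-zero training error
        samples = [s for s in split.train_samples[:80]]
        import copy

        samples = copy.deepcopy(samples)
        for s in samples:
            s.target = 100.0 if s.soil[-1, 0, 0] > 0 else 50.0
        report = baseline_rf(samples, samples)
        assert report.train_rmse < 1.0

    def test_dfnn_parameter_count_matches_shape_walk(self):
        net = DFNN(n_features=423, n_layers=9, width=50)
        expected = 0
        fan_in = 423
        for _ in range(9):
            expected += fan_in * 50 + 50  # dense
            expected += 2 * 50  # batch-norm gamma/beta
            fan_in = 50
        expected += 50 + 1  # linear output
        assert net.count_parameters() == expected


class TestLocationFolds:
    def test_partition_is_disjoint_and_complete(self, sim_records):
        records, _ = sim_records
        folds = location_folds(records, target_year=2010, folds=5, seed=0)
        all_counties = sorted(c for fold in folds for c in fold)
        assert len(all_counties) == len(set(all_counties)) == 30
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_100_eligible_counties_give_folds_of_20(self):
        records = [make_record(f"C{i:03d}", 2010, 100.0) for i in range(100)]
        folds = location_folds(records, 2010, 5, seed=1)
        assert all(len(f) == 20 for f in folds)

    def test_too_few_counties_rejected(self):
        records = [make_record("A", 2010, 100.0)]
        with pytest.raises(ValueError):
            location_folds(records, 2010, 5, seed=0)


class TestLocationKFold:
    def test_two_fold_cv_produces_disjoint_reports(self):
        from yieldnet.experiments import location_kfold
        from yieldnet.synthetic import SimConfig, gen_dataset
        from yieldnet.training import TrainConfig

        config = SimConfig(
            n_counties=12, n_states=3, year_start=2000, year_end=2006, seed=21
        )
        records, _ = gen_dataset(config)
        model = ModelConfig.small(k=3)
        tconfig = TrainConfig(iterations=60, log_every=60, seed=0)
        reports, pooled = location_kfold(
            records, model, tconfig, target_year=2006, folds=2, seed=0
        )
        assert len(reports) == 2
        counties = list(pooled.per_county_abs_error)
        assert len(counties) == len(set(counties)) == 12
        assert pooled.val_rmse > 0


class TestWeatherUpdate:
    def test_proxy_equal_to_truth_gives_flat_series(self, split, trained, small_config):
        params, _ = trained
        batch = samples_to_batch(split.val_samples)
        rows = weather_update_experiment(
            params,
            batch,
            small_config,
            proxy_weather=batch.weather[:, -1].copy(),  # proxy == truth
        )
        rmses = {r["rmse"] for r in rows}
        assert len(rmses) == 1

    def test_final_cutoff_equals_plain_test_prediction(self, split, trained, small_config):
        params, _ = trained
        batch = samples_to_batch(split.val_samples)
        rows = weather_update_experiment(params, batch, small_config)
        plain = predict(params, batch, small_config, "test")
        rmse, _ = evaluate(plain, batch.target)
        assert rows[-1]["cutoff_week"] == 52
        assert rows[-1]["rmse"] == rmse  # bit-identical path
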