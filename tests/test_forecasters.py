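import numpy as np
import pandas as pd
import pytest

from microcast.forecasters import (
    CallableForecaster,
    RecurrentConfig,
    RfConfig,
    VarmaConfig,
    check_stationarity,
    fit,
    fit_varma,
    forecast,
    load_forecaster,
    predict_step,
    save_forecaster,
)
from microcast.io import AbundanceSeries
from microcast.preprocess import WindowConfig, make_windows


def _windows_from_matrix(matrix, lag=3):
    series = AbundanceSeries(
        data=pd.DataFrame(
            np.asarray(matrix, dtype=float),
            columns=[f"g{j}" for j in range(np.shape(matrix)[1])],
            index=[str(t) for t in range(len(matrix))],
        )
    )
    return make_windows(series, WindowConfig(lag=lag))


def _lag_mean_series(T=60, G=2, seed=0):
    """Series where each row is exactly the mean of its three predecessors."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=(3, G))
    rows = list(x)
    for _ in range(T - 3):
        rows.append(np.mean(rows[-3:], axis=0))
    return np.array(rows)


class TestWindowedBackends:
    def test_rf_fits_exact_lag_function_to_low_training_error(self):
        windows = _windows_from_matrix(np.vstack(
            [_lag_mean_series(seed=s) for s in range(3)]
        ))
        model = fit(RfConfig(n_trees=30), windows)
        assert model.training_log["train_mae"] < 0.02

    def test_rf_same_seed_identical_predictions(self):
        rng = np.random.default_rng(1)
        windows = _windows_from_matrix(rng.uniform(size=(30, 2)))
        a = fit(RfConfig(n_trees=10, seed=5), windows)
        b = fit(RfConfig(n_trees=10, seed=5), windows)
        np.testing.assert_array_equal(
            a.predict_batch(windows.X), b.predict_batch(windows.X)
        )

    def test_rf_trained_on_constant_series_predicts_the_constant(self):
        windows = _windows_from_matrix(np.full((20, 2), 0.7))
        model = fit(RfConfig(n_trees=5), windows)
        pred = predict_step(model, np.full((3, 2), 0.7))
        np.testing.assert_allclose(pred, 0.7)

    def test_recurrent_requires_validation_for_early_stopping(self):
        windows = _windows_from_matrix(np.random.default_rng(0).uniform(size=(20, 2)))
        with pytest.raises(ValueError, match="validation"):
            fit(RecurrentConfig(cells=4), windows)

    def test_recurrent_single_epoch_contract(self):
        rng = np.random.default_rng(0)
        windows = _windows_from_matrix(rng.uniform(size=(20, 2)))
        cfg = RecurrentConfig(cells=4, max_epochs=1, patience=None)
        model = fit(cfg, windows)
        assert len(model.training_log["loss"]) == 1

    def test_input_width_mismatch_rejected(self):
        windows = _windows_from_matrix(np.random.default_rng(0).uniform(size=(20, 2)))
        model = fit(RfConfig(n_trees=3), windows)
        with pytest.raises(ValueError, match="window shape"):
            predict_step(model, np.zeros((3, 5)))

    def test_nan_window_rejected(self):
        windows = _windows_from_matrix(np.random.default_rng(0).uniform(size=(20, 2)))
        model = fit(RfConfig(n_trees=3), windows)
        with pytest.raises(ValueError, match="NaN"):
            predict_step(model, np.full((3, 2), np.nan))


class TestPredictStepMocks:
    def test_identity_mock_returns_last_row(self):
        mock = CallableForecaster(lambda w: w[-1], lag=3, genus_names=["a", "b"])
        window = np.arange(6, dtype=float).reshape(3, 2)
        np.testing.assert_array_equal(predict_step(mock, window), [4, 5])

    def test_constant_mock_returns_its_constant(self):
        mock = CallableForecaster(
            lambda w: np.array([7.0]), lag=3, genus_names=["a"]
        )
        np.testing.assert_array_equal(
            predict_step(mock, np.zeros((3, 1))), [7.0]
        )


class TestForecastModes:
    def test_iterative_identity_mock_repeats_last_observation(self):
        mock = CallableForecaster(lambda w: w[-1], lag=3, genus_names=["a"])
        history = np.array([[1.0], [2.0], [3.0]])
        out = forecast(mock, history, steps=4, mode="iterative")
        np.testing.assert_array_equal(out, [[3.0]] * 4)

    def test_iterative_two_step_linear_mock_hand_unrolled(self):
        mock = CallableForecaster(
            lambda w: w.mean(axis=0), lag=3, genus_names=["a"]
        )
        r1, r2, r3 = 1.0, 2.0, 6.0
        out = forecast(mock, np.array([[r1], [r2], [r3]]), 2, "iterative")
        p1 = (r1 + r2 + r3) / 3
        p2 = (r2 + r3 + p1) / 3
        np.testing.assert_allclose(out[:, 0], [p1, p2])

    def test_teacher_forced_is_causal(self):
        rng = np.random.default_rng(3)
        windows = _windows_from_matrix(rng.uniform(size=(40, 2)))
        model = fit(RfConfig(n_trees=10), windows)
        history = rng.uniform(size=(13, 2))
        base = forecast(model, history, steps=10, mode="teacher_forced")
        for t in range(10):
            perturbed = history.copy()
            perturbed[3 + t :] = rng.uniform(size=perturbed[3 + t :].shape)
            alt = forecast(model, perturbed, steps=10, mode="teacher_forced")
            np.testing.assert_array_equal(base[t], alt[t])

    def test_nonpositive_steps_rejected(self):
        mock = CallableForecaster(lambda w: w[-1], lag=3, genus_names=["a"])
        with pytest.raises(ValueError, match="steps"):
            forecast(mock, np.ones((3, 1)), steps=0)

    def test_iterative_with_covariates_requires_future_values(self):
        mock = CallableForecaster(
            lambda w: w[-1, :1], lag=3, genus_names=["a"],
            covariate_names=["temperature"],
        )
        history = np.ones((3, 2))
        with pytest.raises(ValueError, match="future_covariates"):
            forecast(mock, history, steps=2, mode="iterative")
        out = forecast(mock, history, 2, "iterative",
                       future_covariates=np.zeros((2, 1)))
        assert out.shape == (2, 1)


class TestVarma:
    def test_random_walk_flagged_nonstationary_difference_stationary(self):
        rng = np.random.default_rng(0)
        walk = np.cumsum(rng.normal(size=500))
        assert not check_stationarity(walk[:, None])[0]
        assert check_stationarity(np.diff(walk)[:, None])[0]

    def test_white_noise_selects_no_differencing(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(size=(100, 2))
        model = fit_varma(noise, VarmaConfig(grid_p=(0, 1), grid_q=(0, 1),
                                             trend="constant"))
        assert model.d == 0

    def test_ma1_series_prefers_q1_in_most_replicates(self):
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(5000 + rep)
            e = rng.normal(size=201)
            y = e[1:] + 0.7 * e[:-1]
            model = fit_varma(
                y[:, None],
                VarmaConfig(grid_p=(0, 1), grid_q=(0, 1), d=0, trend="constant"),
            )
            wins += model.order[1] == 1
        assert wins >= 8

    def test_differenced_forecast_recovers_linear_trend_slope(self):
        t = np.arange(120.0)
        matrix = np.column_stack(
            [2.0 + 0.5 * t + 0.01 * np.sin(t), 1.0 + 0.3 * t + 0.01 * np.cos(t)]
        )
        model = fit_varma(matrix, VarmaConfig(grid_p=(0, 1), grid_q=(0, 1)))
        assert model.d == 1
        fc = model.forecast_from_training_end(10)
        assert np.diff(fc[:, 0]).mean() == pytest.approx(0.5, abs=0.05)
        assert np.diff(fc[:, 1]).mean() == pytest.approx(0.3, abs=0.05)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="20"):
            fit_varma(np.ones((10, 2)))

    def test_constant_columns_filtered_and_forecast_as_constant(self):
        rng = np.random.default_rng(2)
        matrix = np.column_stack([rng.normal(size=60), np.full(60, 4.0)])
        model = fit_varma(matrix, VarmaConfig(grid_p=(0, 1), grid_q=(0, 1),
                                              trend="constant"))
        fc = model.forecast_from_training_end(3)
        np.testing.assert_allclose(fc[:, 1], 4.0)


class TestPersistence:
    @pytest.mark.parametrize("backend_cfg", [
        RfConfig(n_trees=5),
        RecurrentConfig(cells=4, max_epochs=3, patience=None),
    ], ids=["rf", "lstm"])
    def test_save_load_round_trip(self, backend_cfg, tmp_path):
        rng = np.random.default_rng(0)
        windows = _windows_from_matrix(rng.uniform(size=(25, 2)))
        model = fit(backend_cfg, windows)
        save_forecaster(model, tmp_path / "m", scaler_hash="abc")
        loaded = load_forecaster(tmp_path / "m", expect_scaler_hash="abc")
        np.testing.assert_allclose(
            model.predict_batch(windows.X), loaded.predict_batch(windows.X)
        )

    def test_scaler_hash_mismatch_refused(self, tmp_path):
        rng = np.random.default_rng(0)
        windows = _windows_from_matrix(rng.uniform(size=(25, 2)))
        model = fit(RfConfig(n_trees=3), windows)
        save_forecaster(model, tmp_path / "m", scaler_hash="abc")
        with pytest.raises(ValueError, match="scaler hash"):
            load_forecaster(tmp_path / "m", expect_scaler_hash="other")
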